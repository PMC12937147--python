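"""Training-set augmentation: horizontal flip plus six fixed rotations.

The default scheme emits, per input pair, the original, its horizontal flip,
and one rotation per angle in (45°, 90°, 135°, 180°, 234°, 270°) — an exact
8x expansion, applied identically to both views of a pair.  The transforms
are NOT composed (flip x rotation would give 14x); the factor is always
``include_original + include_flip + len(angles)``.

The 234° angle is kept verbatim as the default (it is plausibly a transposed
225°, but fidelity wins); the list is configurable.  Right-angle rotations
and flips are exact array reorderings; other angles rotate about the image
center with bilinear sampling and constant fill, keeping the frame size.

Augmentation is a training-set operation only: ``augment_training_set``
refuses samples tagged as test/validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .data import PairedSample

__all__ = ["AugmentConfig", "augment_pair", "augment_training_set"]

DEFAULT_ANGLES = (45.0, 90.0, 135.0, 180.0, 234.0, 270.0)


@dataclass
class AugmentConfig:
    angles: tuple[float, ...] = DEFAULT_ANGLES
    include_flip: bool = True
    include_original: bool = True
    fill_value: float = 0.0

    def __post_init__(self):
        self.angles = tuple(float(a) for a in self.angles)
        if len(set(self.angles)) != len(self.angles):
            raise ValueError("rotation angles must be distinct")
        if not (self.include_original or self.include_flip or self.angles):
            raise ValueError("augmentation config enables no transform at all")

    @property
    def factor(self) -> int:
        """Outputs per input: original + flip + one per angle."""
        return int(self.include_original) + int(self.include_flip) + len(self.angles)


def _rotate(img: np.ndarray, angle: float, fill: float) -> np.ndarray:
    k = angle % 360.0
    if k == 0.0:
        return img.copy()
    if k in (90.0, 180.0, 270.0):  # exact, histogram-preserving
        return np.ascontiguousarray(np.rot90(img, k=int(k // 90)))
    return _sk_rotate(img, angle, resize=False, order=1, cval=fill,
                      preserve_range=True).astype(img.dtype)


def augment_pair(sample: PairedSample, config: AugmentConfig | None = None
                 ) -> list[PairedSample]:
    """Apply the configured transform set to one pair.

    Every transform is applied identically to the CC and MLO images; labels,
    case identity and partition tags are preserved.
    """
    config = config or AugmentConfig()

    def make(cc, mlo, tag):
        return PairedSample(
            case_id=sample.case_id, laterality=sample.laterality,
            cc=cc, mlo=mlo, label=sample.label, partition=sample.partition,
            augmented=tag != "original",
            meta={**sample.meta, "augmentation": tag})

    out = []
    if config.include_original:
        out.append(make(sample.cc.copy(), sample.mlo.copy(), "original"))
    if config.include_flip:
        out.append(make(np.ascontiguousarray(sample.cc[:, ::-1]),
                        np.ascontiguousarray(sample.mlo[:, ::-1]), "hflip"))
    for angle in config.angles:
        out.append(make(_rotate(sample.cc, angle, config.fill_value),
                        _rotate(sample.mlo, angle, config.fill_value),
                        f"rot{angle:g}"))
    return out


def augment_training_set(samples: Sequence[PairedSample],
                         config: AugmentConfig | None = None
                         ) -> list[PairedSample]:
    """Augment a training partition; output count = len(samples) * factor.

    Samples explicitly tagged as belonging to a held-out partition are
    rejected — test data must never be augmented.
    """
    config = config or AugmentConfig()
    offenders = [s.case_id for s in samples if s.partition in ("test", "val")]
    if offenders:
        raise ValueError(
            f"augmentation applied to held-out samples (cases {sorted(set(offenders))}); "
            "augment the training partition only")
    out: list[PairedSample] = []
    for s in samples:
        out.extend(augment_pair(s, config))
    return out
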