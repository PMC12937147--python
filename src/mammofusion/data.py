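"""Core record types and manifest I/O.

A *case* is one breast (case id + laterality); its craniocaudal (CC) and
mediolateral-oblique (MLO) projections form the network's input unit.
Manifests are plain CSV with the fixed header
``case_id,laterality,view,label,path``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

LATERALITIES = ("L", "R")
VIEWS = ("CC", "MLO")
LABELS = ("benign", "malignant")
MANIFEST_COLUMNS = ["case_id", "laterality", "view", "label", "path"]

LABEL_TO_INT = {"benign": 0, "malignant": 1}


@dataclass
class MammogramRecord:
    """One mammographic image with its identifying metadata.

    ``pixels`` is a 2-D float array on the 8-bit-like [0, 255] scale.
    ``masks`` optionally carries the generator's ground-truth channels
    (``breast``, ``pectoral``, ``lesion``) for oracle checks; real data has
    no masks.
    """

    case_id: str
    laterality: str
    view: str
    label: str
    pixels: np.ndarray
    masks: dict[str, np.ndarray] | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}: {self.laterality!r}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}: {self.view!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}: {self.label!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")

    @property
    def label_int(self) -> int:
        return LABEL_TO_INT[self.label]

    @property
    def key(self) -> tuple[str, str]:
        """Pairing key: (case_id, laterality)."""
        return (self.case_id, self.laterality)


@dataclass
class PairedSample:
    """The (CC, MLO) image pair of one breast plus its binary label.

    After preprocessing both images are square float arrays in [0, 1];
    before preprocessing they may be on any scale (the ``augment`` and
    ``model`` stages only require matching square shapes).
    """

    case_id: str
    laterality: str
    cc: np.ndarray
    mlo: np.ndarray
    label: int
    partition: str = "unassigned"  # {train, val, test, unassigned}
    augmented: bool = False
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.cc = np.asarray(self.cc, dtype=np.float32)
        self.mlo = np.asarray(self.mlo, dtype=np.float32)
        if self.cc.ndim != 2 or self.mlo.ndim != 2:
            raise ValueError("cc and mlo must be 2-D arrays")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (benign) or 1 (malignant): {self.label}")


def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    return df


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF, or DICOM when pydicom is present)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom  # optional dependency

        arr = pydicom.dcmread(path).pixel_array.astype(np.float64)
    else:
        arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return arr


def load_records(manifest: pd.DataFrame, root: str | Path = ".") -> list[MammogramRecord]:
    root = Path(root)
    records = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        records.append(MammogramRecord(
            case_id=row.case_id, laterality=row.laterality, view=row.view,
            label=row.label, pixels=read_image(p)))
    return records
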