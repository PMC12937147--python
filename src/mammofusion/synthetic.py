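"""Paired CC/MLO phantom mammogram generator.

The generator produces crude but structurally faithful digital phantoms:

* a half-elliptical breast region anchored on the chest-wall edge (left edge
  for left laterality; right-laterality images are rendered mirrored),
* in MLO views only, a bright triangular pectoral-muscle wedge in the upper
  posterior corner,
* lesion blobs whose *boundary irregularity* encodes the class — malignant
  lesions have strongly perturbed radial boundaries, benign blobs (when
  present) are smooth and low-contrast — rendered in BOTH views of a case at
  cross-view-consistent positions up to a configurable jitter,
* smooth tissue texture plus optional additive Gaussian noise.

Alongside pixels, each record carries ground-truth mask channels
(``breast``, ``pectoral``, ``lesion``) and the lesion parameters used, so
that downstream stages (Otsu extraction, pectoral removal, Grad-CAM focus)
can be checked against a known answer.  The phantoms make no attempt at
radiographically realistic texture; they exist to exercise the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .data import MANIFEST_COLUMNS, LABELS, MammogramRecord, write_manifest

__all__ = ["PhantomSpec", "generate_case", "generate_dataset", "write_dataset"]


@dataclass
class PhantomSpec:
    """Parameters of the phantom family.

    Geometry is expressed relative to ``image_size`` so the same spec
    renders consistently at any resolution.
    """

    image_size: int = 512
    breast_axis_ratio: tuple[float, float] = (1.15, 1.45)  # vertical/horizontal semi-axis
    pectoral_fraction: float = 0.35        # fraction of MLO height under the wedge
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (0.03, 0.06)  # fraction of image size
    lesion_irregularity: tuple[float, float] = (0.05, 0.35)  # (benign, malignant) amplitude
    lesion_contrast: float = 70.0          # additive intensity of malignant lesions
    benign_lesion_prob: float = 0.5        # chance a benign case shows a smooth blob
    benign_contrast_factor: float = 0.55   # benign blob contrast relative to malignant
    cross_view_jitter: float = 0.015       # lesion-position displacement, fraction of size
    view_asymmetry: float = 0.0            # 0: equal views; 1: lesion in one view only
    view_asymmetry_mode: str = "mlo"       # which view is attenuated: "mlo", "cc", "random"
    tissue_intensity: float = 110.0
    texture_sd: float = 18.0               # smooth within-breast texture amplitude
    pectoral_intensity: float = 185.0
    noise_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0.0 < self.pectoral_fraction < 1.0):
            raise ValueError("pectoral_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("breast_axis_ratio", "lesion_radius_range", "lesion_irregularity"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range is empty: ({lo}, {hi})")
        lo, hi = self.lesion_count_range
        if hi < lo or lo < 0:
            raise ValueError(f"lesion_count_range invalid: ({lo}, {hi})")
        if not (0.0 <= self.view_asymmetry <= 1.0):
            raise ValueError("view_asymmetry must lie in [0, 1]")
        if self.view_asymmetry_mode not in ("mlo", "cc", "random"):
            raise ValueError("view_asymmetry_mode must be 'mlo', 'cc' or 'random'")


@dataclass
class _Lesion:
    """One lesion: position in breast-relative coordinates plus shape."""

    u: float               # posterior->anterior position, fraction of semi-axis a
    v: float               # vertical position, fraction of semi-axis b
    radius: float          # pixels
    irregularity: float
    contrast: float
    harmonics: np.ndarray  # (k, 2) amplitude/phase pairs for the radial perturbation
    smooth_profile: bool


def _radial_boundary(lesion: _Lesion, theta: np.ndarray) -> np.ndarray:
    """r(theta): base radius modulated by random-phase harmonics."""
    pert = np.zeros_like(theta)
    for k, (amp, phase) in enumerate(lesion.harmonics, start=2):
        pert += amp * np.cos(k * theta + phase)
    return lesion.radius * (1.0 + lesion.irregularity * pert)


def _render_lesion(img: np.ndarray, mask: np.ndarray, lesion: _Lesion,
                   cy: float, cx: float, contrast: float) -> None:
    r_max = lesion.radius * (1.0 + abs(lesion.irregularity) * len(lesion.harmonics))
    size = img.shape[0]
    y0, y1 = int(max(0, cy - r_max - 2)), int(min(size, cy + r_max + 3))
    x0, x1 = int(max(0, cx - r_max - 2)), int(min(size, cx + r_max + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    rb = _radial_boundary(lesion, theta)
    inside = rad <= rb
    if lesion.smooth_profile:
        profile = np.clip(1.0 - (rad / np.maximum(rb, 1e-9)) ** 2, 0.0, 1.0)
    else:
        profile = np.clip(1.0 - 0.35 * (rad / np.maximum(rb, 1e-9)) ** 2, 0.0, 1.0)
    img[y0:y1, x0:x1] += contrast * profile * inside
    mask[y0:y1, x0:x1] |= inside


def _breast_geometry(spec: PhantomSpec, rng: np.random.Generator):
    size = spec.image_size
    b = rng.uniform(0.36, 0.44) * size                      # vertical semi-axis
    ratio = rng.uniform(*spec.breast_axis_ratio)
    a = b / ratio                                           # horizontal semi-axis
    cy = size / 2.0 + rng.uniform(-0.02, 0.02) * size
    return a, b, cy


def _sample_lesions(spec: PhantomSpec, label: str, rng: np.random.Generator,
                    geometry) -> list[_Lesion]:
    size = spec.image_size
    a, b, _cy = geometry
    if label == "malignant":
        n = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
        irr, contrast, smooth = spec.lesion_irregularity[1], spec.lesion_contrast, False
    else:
        n = int(rng.random() < spec.benign_lesion_prob)
        irr = spec.lesion_irregularity[0]
        contrast = spec.lesion_contrast * spec.benign_contrast_factor
        smooth = True
    lesions: list[_Lesion] = []
    bounds: list[float] = []   # per-lesion worst-case radial extent, pixels
    jitter_px = spec.cross_view_jitter * size
    for _ in range(n):
        radius = rng.uniform(*spec.lesion_radius_range) * size
        harmonics = np.column_stack([
            rng.uniform(0.25, 1.0, 5) / np.arange(2, 7),
            rng.uniform(0, 2 * np.pi, 5),
        ])
        placed = False
        while not placed:
            bound = radius * (1.0 + irr * harmonics[:, 0].sum())
            margin = max(0.15, 1.0 - (bound + jitter_px + 2) / min(a, b))
            for _attempt in range(128):  # rejection sampling keeps blobs disjoint
                u = rng.uniform(0.08, margin)
                v = rng.uniform(-1.0, 1.0) * np.sqrt(max(margin ** 2 - u ** 2, 0.0))
                sep_ok = all(
                    (u - q.u) ** 2 * a ** 2 + (v - q.v) ** 2 * b ** 2 >
                    (bound + qb + 2 * jitter_px + 3) ** 2
                    for q, qb in zip(lesions, bounds))
                if sep_ok:
                    placed = True
                    break
            if not placed:  # crowded breast: shrink and retry
                radius *= 0.7
        lesions.append(_Lesion(u, v, radius, irr, contrast, harmonics, smooth))
        bounds.append(bound)
    return lesions


def _render_view(spec: PhantomSpec, view: str, laterality: str, label: str,
                 lesions: list[_Lesion], geometry, texture_rng: np.random.Generator,
                 jitter_rng: np.random.Generator, noise_rng: np.random.Generator,
                 attenuated_view: str = "MLO"):
    size = spec.image_size
    a, b, cy = geometry
    img = np.zeros((size, size), dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    # chest wall on the left edge; mirrored at the end for right laterality
    breast = ((xx / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0
    img[breast] = spec.tissue_intensity
    if spec.texture_sd > 0:
        texture = ndimage.gaussian_filter(
            texture_rng.standard_normal((size, size)), sigma=size / 24.0)
        texture *= spec.texture_sd / max(texture.std(), 1e-12)
        img[breast] += texture[breast]

    pectoral = np.zeros((size, size), dtype=bool)
    if view == "MLO":
        h = spec.pectoral_fraction * size
        w = 0.55 * h
        pectoral = (yy / h + xx / w) <= 1.0
        img[pectoral] = spec.pectoral_intensity
        breast = breast & ~pectoral

    lesion_mask = np.zeros((size, size), dtype=bool)
    view_gain = (1.0 - spec.view_asymmetry) if view == attenuated_view else 1.0
    for lesion in lesions:
        cyl = cy + lesion.v * b
        cxl = lesion.u * a
        if view == "MLO" and spec.cross_view_jitter > 0:
            cyl += jitter_rng.uniform(-1, 1) * spec.cross_view_jitter * size
            cxl += jitter_rng.uniform(-1, 1) * spec.cross_view_jitter * size
        _render_lesion(img, lesion_mask, lesion, cyl, cxl, lesion.contrast * view_gain)
    lesion_mask &= breast | pectoral
    img[~(breast | pectoral)] = 0.0

    if spec.noise_sd > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 255.0)

    masks = {"breast": breast, "pectoral": pectoral, "lesion": lesion_mask}
    if laterality == "R":
        img = img[:, ::-1].copy()
        masks = {k: v[:, ::-1].copy() for k, v in masks.items()}
    return img, masks


def generate_case(spec: PhantomSpec, label: str, rng: np.random.Generator,
                  case_id: str = "case0000",
                  laterality: str | None = None) -> tuple[MammogramRecord, MammogramRecord]:
    """Render the CC and MLO phantom of one breast.

    Both records share ``case_id``, ``laterality`` and ``label``; lesions are
    placed at cross-view-consistent breast-relative coordinates, displaced in
    the MLO rendering by at most ``spec.cross_view_jitter``.
    """
    spec.validate()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}: {label!r}")
    if laterality is None:
        laterality = "L" if rng.random() < 0.5 else "R"
    geometry = _breast_geometry(spec, rng)
    lesions = _sample_lesions(spec, label, rng, geometry)
    if spec.view_asymmetry_mode == "random":
        attenuated = "MLO" if rng.random() < 0.5 else "CC"
    else:
        attenuated = spec.view_asymmetry_mode.upper()
    texture_seed, jitter_seed, noise_cc, noise_mlo = rng.integers(0, 2 ** 31, size=4)

    records = []
    for view, noise_seed in (("CC", noise_cc), ("MLO", noise_mlo)):
        img, masks = _render_view(
            spec, view, laterality, label, lesions, geometry,
            texture_rng=np.random.default_rng(texture_seed),
            jitter_rng=np.random.default_rng(jitter_seed),
            noise_rng=np.random.default_rng(noise_seed),
            attenuated_view=attenuated)
        records.append(MammogramRecord(
            case_id=case_id, laterality=laterality, view=view, label=label,
            pixels=img, masks=masks,
            meta={"lesions": lesions, "geometry": geometry}))
    return records[0], records[1]


def generate_dataset(spec: PhantomSpec, n_benign: int, n_malignant: int,
                     ) -> tuple[list[MammogramRecord], pd.DataFrame]:
    """Generate ``n_benign + n_malignant`` cases (two records each).

    Returns the records plus a manifest table with the fixed column set
    ``case_id,laterality,view,label,path`` (in-memory placeholder paths; use
    :func:`write_dataset` to materialise PNGs).  Fully determined by
    ``spec.seed``.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("case counts must be >= 0")
    spec.validate()
    master = np.random.default_rng(spec.seed)
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    records: list[MammogramRecord] = []
    rows = []
    for i, label in enumerate(labels):
        case_id = f"case{i:04d}"
        rng = np.random.default_rng(master.integers(0, 2 ** 31))
        cc, mlo = generate_case(spec, label, rng, case_id=case_id)
        for rec in (cc, mlo):
            records.append(rec)
            rows.append({
                "case_id": rec.case_id, "laterality": rec.laterality,
                "view": rec.view, "label": rec.label,
                "path": f"{rec.case_id}_{rec.laterality}_{rec.view}.png"})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return records, manifest


def write_dataset(records: list[MammogramRecord], manifest: pd.DataFrame,
                  out_dir: str | Path, with_masks: bool = False) -> Path:
    """Write PNG images, the CSV manifest and (optionally) NPZ mask bundles."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, path in zip(records, manifest["path"]):
        iio.imwrite(out_dir / path, np.round(rec.pixels).astype(np.uint8))
        if with_masks and rec.masks is not None:
            np.savez_compressed(out_dir / (Path(path).stem + "_masks.npz"), **rec.masks)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path
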