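"""Mammogram preprocessing chain.

Per view: orientation normalisation (chest wall to the left edge) →
Otsu-based breast extraction → pectoral-muscle suppression (MLO only) →
CLAHE → bilinear resize to ``target_size`` → rescale to [0, 1].  CC and MLO
records are paired by (case id, laterality); unpaired views are excluded.

The pectoral-muscle estimator is a deliberately simple corner-component
heuristic (double Otsu in the upper-posterior quadrant, keep the component
touching the corner, fit a straight boundary line, zero above it).  It is
exposed behind its own function so a stronger algorithm can be swapped in.

CLAHE is implemented here directly (clipped per-tile histograms with
redistribution, bilinear blending of the per-tile lookup tables) operating on
the 8-bit [0, 255] intensity convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .data import MammogramRecord, PairedSample

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig", "otsu_threshold", "extract_breast_region",
    "remove_pectoral_muscle", "apply_clahe", "pair_views", "preprocess_pair",
    "preprocess_records",
]


@dataclass
class PreprocessConfig:
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8          # tiles per axis
    target_size: int = 256
    pectoral_removal_enabled: bool = True
    orientation_normalize: bool = True

    def __post_init__(self):
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.clahe_tile_grid < 1:
            raise ValueError("clahe_tile_grid must be >= 1")


# ---------------------------------------------------------------------------
# Otsu thresholding and breast extraction
# ---------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximising between-class variance over a 256-bin histogram.

    Intensities are binned on [0, 256); the returned value t* is the upper
    edge of the background class, i.e. foreground = ``image > t*``.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.ptp(image) == 0:
        raise ValueError("otsu_threshold: constant image has no threshold")
    hist, edges = np.histogram(image, bins=256, range=(0.0, 256.0))
    p = hist.astype(np.float64) / hist.sum()
    levels = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    m = np.cumsum(p * levels)
    mt = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mt * w0 - m) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    t_idx = int(np.argmax(sigma_b))
    return float(edges[t_idx + 1])  # upper edge of the last background bin


@dataclass
class BreastRegion:
    """Result of breast extraction: cropped image, mask and source bbox."""

    image: np.ndarray
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


def extract_breast_region(image: np.ndarray) -> BreastRegion:
    """Keep the largest Otsu-foreground component and crop to its bbox."""
    image = np.asarray(image, dtype=np.float64)
    t = otsu_threshold(image)
    fg = image > t
    if not fg.any():
        raise ValueError("extract_breast_region: empty foreground after Otsu")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    mask = labels == keep
    cleaned = np.where(mask, image, 0.0)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    r0, r1, c0, c1 = bbox
    return BreastRegion(cleaned[r0:r1, c0:c1], mask[r0:r1, c0:c1], bbox)


# ---------------------------------------------------------------------------
# pectoral muscle suppression (MLO)
# ---------------------------------------------------------------------------

def remove_pectoral_muscle(mlo_image: np.ndarray, corner_tol: int = 3,
                           min_area_frac: float = 0.002) -> np.ndarray:
    """Zero the estimated pectoral wedge of an orientation-normalised MLO view.

    Estimator: within the upper-posterior (top-left) quadrant, isolate the
    brightest Otsu class with a second Otsu pass, keep the connected
    component touching the top-left corner, fit a straight line to its lower
    boundary and zero everything above-left of that line.  If no candidate
    component touches the corner the input is returned unchanged with a
    logged warning — which also makes the operation idempotent.
    """
    img = np.asarray(mlo_image, dtype=np.float64)
    h, w = img.shape
    quad = img[: h // 2, : w // 2]
    try:
        t1 = otsu_threshold(quad)
    except ValueError:
        logger.warning("remove_pectoral_muscle: degenerate quadrant; image unchanged")
        return img.copy()
    # a second Otsu pass isolates the brightest class when the first pass
    # only separated background from tissue; skipped when the bright class
    # is already homogeneous
    bright = quad[quad > t1]
    if bright.size >= 2 and np.ptp(bright) > 0:
        t2 = otsu_threshold(bright)
    else:
        t2 = t1
    cand = quad > t2
    labels, n = ndimage.label(cand)
    corner_labels = np.unique(labels[:corner_tol, :corner_tol])
    corner_labels = corner_labels[corner_labels > 0]
    if corner_labels.size == 0:
        logger.warning("remove_pectoral_muscle: no component touches the corner; "
                       "image unchanged")
        return img.copy()
    comp = np.isin(labels, corner_labels)
    if comp.sum() < min_area_frac * quad.size:
        logger.warning("remove_pectoral_muscle: corner component too small; "
                       "image unchanged")
        return img.copy()
    # rightmost column of the component per row -> straight boundary fit
    rows = np.flatnonzero(comp.any(axis=1))
    cols_right = np.array([np.flatnonzero(comp[r])[-1] for r in rows], dtype=np.float64)
    if rows.size >= 2:
        slope, intercept = np.polyfit(rows.astype(np.float64), cols_right, deg=1)
    else:
        slope, intercept = 0.0, cols_right[0]
    out = img.copy()
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    wedge = xx <= slope * yy + intercept + 1.0
    if slope < 0:  # the wedge ends where the boundary line crosses column 0
        wedge &= yy <= -intercept / slope + 1.0
    else:  # non-tapering fit: restrict to the component's row extent
        wedge &= yy <= rows[-1] + 1.0
    out[wedge] = 0.0
    return out


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def apply_clahe(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on [0, 255].

    Per tile, the 256-bin histogram is clipped at
    ``clip_limit * tile_area / 256`` and the excess redistributed uniformly;
    the tile's lookup table is the rescaled cumulative histogram.  Pixel
    outputs blend the four surrounding tile tables bilinearly (border tiles
    replicated), so at a tile center the mapping is exactly that tile's own
    equalisation.
    """
    config = config or PreprocessConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("apply_clahe expects intensities in [0, 255]")
    h, w = img.shape
    g = config.clahe_tile_grid
    vals = np.clip(img, 0, 255).astype(np.int64)

    # per-tile clipped-histogram lookup tables
    row_edges = np.linspace(0, h, g + 1).astype(int)
    col_edges = np.linspace(0, w, g + 1).astype(int)
    luts = np.zeros((g, g, 256), dtype=np.float64)
    for i in range(g):
        for j in range(g):
            tile = vals[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            clip_at = max(config.clahe_clip_limit * area / 256.0, 1.0)
            excess = np.maximum(hist - clip_at, 0.0).sum()
            hist = np.minimum(hist, clip_at) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[i, j] = cdf * (255.0 / area)

    # bilinear blend of tile mappings, indexed by tile centers
    centers_r = 0.5 * (row_edges[:-1] + row_edges[1:])
    centers_c = 0.5 * (col_edges[:-1] + col_edges[1:])
    ry = np.interp(np.arange(h) + 0.5, centers_r, np.arange(g))
    cx = np.interp(np.arange(w) + 0.5, centers_c, np.arange(g))
    iy0 = np.clip(np.floor(ry).astype(int), 0, g - 1)
    ix0 = np.clip(np.floor(cx).astype(int), 0, g - 1)
    iy1 = np.minimum(iy0 + 1, g - 1)
    ix1 = np.minimum(ix0 + 1, g - 1)
    wy = (ry - iy0)[:, None]
    wx = (cx - ix0)[None, :]
    IY0, IX0 = np.broadcast_arrays(iy0[:, None], ix0[None, :])
    IY1, IX1 = np.broadcast_arrays(iy1[:, None], ix1[None, :])
    out = ((1 - wy) * (1 - wx) * luts[IY0, IX0, vals]
           + (1 - wy) * wx * luts[IY0, IX1, vals]
           + wy * (1 - wx) * luts[IY1, IX0, vals]
           + wy * wx * luts[IY1, IX1, vals])
    return np.clip(out, 0.0, 255.0)


# ---------------------------------------------------------------------------
# pairing and the full chain
# ---------------------------------------------------------------------------

def pair_views(records: list[MammogramRecord]
               ) -> tuple[list[tuple[MammogramRecord, MammogramRecord]],
                          list[MammogramRecord]]:
    """Pair CC and MLO records by (case id, laterality).

    Returns (pairs, exclusions).  Cross-laterality pairing is never
    performed; a duplicated (case, laterality, view) triplet is an error.
    """
    seen: dict[tuple[str, str, str], MammogramRecord] = {}
    dups = []
    for rec in records:
        key = (rec.case_id, rec.laterality, rec.view)
        if key in seen:
            dups.append(key)
        seen[key] = rec
    if dups:
        raise ValueError(f"duplicate (case, laterality, view) records: {sorted(set(dups))}")
    pairs, exclusions = [], []
    keys = sorted({rec.key for rec in records}, key=str)
    for case_id, lat in keys:
        cc = seen.get((case_id, lat, "CC"))
        mlo = seen.get((case_id, lat, "MLO"))
        if cc is not None and mlo is not None:
            pairs.append((cc, mlo))
        else:
            exclusions.extend(r for r in (cc, mlo) if r is not None)
    return pairs, exclusions


def _resize_bilinear(img: np.ndarray, size: int) -> np.ndarray:
    return _sk_resize(img, (size, size), order=1, anti_aliasing=False,
                      preserve_range=True, mode="edge")


def _preprocess_view(record: MammogramRecord, config: PreprocessConfig
                     ) -> tuple[np.ndarray, dict]:
    img = record.pixels
    flipped = False
    if config.orientation_normalize and record.laterality == "R":
        img = img[:, ::-1]
        flipped = True
    region = extract_breast_region(img)
    out = region.image
    if record.view == "MLO" and config.pectoral_removal_enabled:
        out = remove_pectoral_muscle(out)
    out = apply_clahe(out, config)
    crop_h = region.bbox[1] - region.bbox[0]
    crop_w = region.bbox[3] - region.bbox[2]
    out = _resize_bilinear(out, config.target_size) / 255.0
    transform = {
        "flipped": flipped,
        "source_width": img.shape[1],
        "bbox": region.bbox,
        "scale": (config.target_size / crop_h, config.target_size / crop_w),
    }
    return out.astype(np.float32), transform


def preprocess_pair(cc_record: MammogramRecord, mlo_record: MammogramRecord,
                    config: PreprocessConfig | None = None) -> PairedSample:
    """Run the full chain on one CC/MLO record pair."""
    config = config or PreprocessConfig()
    if cc_record.key != mlo_record.key or cc_record.label != mlo_record.label:
        raise ValueError("records do not form a valid pair")
    if (cc_record.view, mlo_record.view) != ("CC", "MLO"):
        raise ValueError("expected one CC and one MLO record, in that order")
    cc, t_cc = _preprocess_view(cc_record, config)
    mlo, t_mlo = _preprocess_view(mlo_record, config)
    return PairedSample(
        case_id=cc_record.case_id, laterality=cc_record.laterality,
        cc=cc, mlo=mlo, label=cc_record.label_int,
        meta={"transform_cc": t_cc, "transform_mlo": t_mlo})


def preprocess_records(records: list[MammogramRecord],
                       config: PreprocessConfig | None = None
                       ) -> tuple[list[PairedSample], list[MammogramRecord]]:
    """Pair all records and preprocess every complete pair."""
    config = config or PreprocessConfig()
    pairs, exclusions = pair_views(records)
    samples = [preprocess_pair(cc, mlo, config) for cc, mlo in pairs]
    return samples, exclusions


def map_point_through_transform(point: tuple[float, float], transform: dict,
                                target_size: int = 256) -> tuple[float, float]:
    """Map a (row, col) source-image point through a view's geometric chain.

    Used to carry generator ground-truth coordinates (lesion centers) into
    the preprocessed frame: horizontal flip (if applied) → crop to the
    breast bbox → anisotropic scale to the target square.
    """
    r, c = point
    if transform["flipped"]:
        c = transform["source_width"] - 1 - c
    r0, r1, c0, c1 = transform["bbox"]
    sr, sc = transform["scale"]
    return ((r - r0) * sr, (c - c0) * sc)
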