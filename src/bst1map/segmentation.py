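"""Tissue segmentation from the inversion-recovery nulling image, and ROI
summaries of T1 maps.

At an inversion time near the fibroglandular-tissue (FGT) null, adipose
tissue (AT, short T1) has already recovered substantial signal while FGT
signal is close to its minimum, so a simple intensity threshold inside the
body separates the two compartments: AT is the bright class, FGT is the
complement of AT within the body.  The skin/chest-wall exclusion that a
reader would perform manually is represented by the supplied body mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import ImageVolume, T1Map

__all__ = [
    "TissueMasks",
    "ROISummary",
    "segment_adipose",
    "segment_fibroglandular",
    "roi_mean",
]


@dataclass
class TissueMasks:
    """Adipose / fibroglandular / body masks on one grid.

    Invariants: AT and FGT are disjoint and both contained in the body.
    """

    at_mask: np.ndarray
    fgt_mask: np.ndarray
    body_mask: np.ndarray

    def __post_init__(self) -> None:
        self.at_mask = np.asarray(self.at_mask, dtype=bool)
        self.fgt_mask = np.asarray(self.fgt_mask, dtype=bool)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if not (self.at_mask.shape == self.fgt_mask.shape == self.body_mask.shape):
            raise ValueError("masks must share one grid")
        if (self.at_mask & self.fgt_mask).any():
            raise ValueError("AT and FGT masks overlap")
        if (self.at_mask & ~self.body_mask).any() or (self.fgt_mask & ~self.body_mask).any():
            raise ValueError("tissue masks must lie within the body mask")


@dataclass
class ROISummary:
    """Mean/SD of valid T1 values over one region (sample SD, n-1)."""

    roi: str
    method: str
    mean_t1_ms: float
    sd_t1_ms: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("ROISummary needs at least one voxel")
        if self.sd_t1_ms < 0:
            raise ValueError("sd must be >= 0")


def segment_adipose(
    ir_null_volume: ImageVolume,
    body_mask: np.ndarray | None = None,
    strategy: str = "otsu",
    fraction: float = 0.5,
) -> np.ndarray:
    """Threshold the nulling image within the body to extract adipose tissue.

    ``strategy`` is ``"otsu"`` (default; threshold from the within-body
    intensity histogram) or ``"fraction"`` (threshold at ``fraction`` of
    the within-body maximum).  Raises on an empty body mask or an image
    with no intensity contrast (nothing to segment).
    """
    img = ir_null_volume.magnitude()
    if body_mask is None:
        body_mask = np.ones(img.shape, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if body_mask.shape != img.shape:
        raise ValueError("body mask grid differs from image grid")
    if not body_mask.any():
        raise ValueError("body mask is empty")
    vals = img[body_mask]
    if not np.isfinite(vals).all():
        vals = vals[np.isfinite(vals)]
    if vals.size == 0 or vals.max() <= 0 or np.ptp(vals) == 0:
        raise ValueError("no adipose tissue detectable: image has no contrast")
    if strategy == "otsu":
        thresh = threshold_otsu(vals)
    elif strategy == "fraction":
        if not (0 < fraction < 1):
            raise ValueError("fraction must be in (0, 1)")
        thresh = fraction * vals.max()
    else:
        raise ValueError("strategy must be 'otsu' or 'fraction'")
    return body_mask & (img > thresh)


def segment_fibroglandular(at_mask: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    """FGT = body and not AT (set complement within the body)."""
    at_mask = np.asarray(at_mask, dtype=bool)
    body_mask = np.asarray(body_mask, dtype=bool)
    if at_mask.shape != body_mask.shape:
        raise ValueError("masks on different grids")
    return body_mask & ~at_mask


def roi_mean(t1_map: T1Map, mask: np.ndarray, roi: str = "") -> ROISummary:
    """Mean and sample SD of T1 over the valid voxels of a region.

    Invalid (NaN) voxels are excluded; raises if none remain.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t1_map.shape:
        raise ValueError("mask grid differs from the T1 map grid")
    sel = mask & t1_map.valid_mask
    vals = t1_map.t1_ms[sel]
    if vals.size == 0:
        raise ValueError(f"ROI {roi!r} contains no valid voxels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ROISummary(
        roi=roi,
        method=t1_map.method,
        mean_t1_ms=float(vals.mean()),
        sd_t1_ms=sd,
        n_voxels=int(vals.size),
    )
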