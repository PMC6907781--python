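"""ROI metabolite ratios, response classification, tumor volumes.

The treatment-response biomarker is the tumor Lac/Bic ratio: lactate
labeling reflects glycolysis, bicarbonate labeling oxidative
phosphorylation, so their ratio indexes the Warburg shift.  ROI ratios
default to ratios of sums over the mask (robust to low-signal voxels);
a mean-of-voxel-ratios mode is available for comparison since either
convention is defensible for manual-ROI analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import (
    EmptyInputError,
    EmptyRoiError,
    InvalidParameterError,
    ShapeError,
    UndefinedGrowthError,
)
from .recon import MetaboliteMapSet

__all__ = [
    "RoiMask",
    "RatioSet",
    "VolumeEstimate",
    "roi_ratios",
    "ratio_set_from_sums",
    "classify_response",
    "tumor_volume",
    "growth_rate",
    "tumor_mask_from_enhancement",
]


@dataclass(frozen=True)
class RoiMask:
    """Boolean region-of-interest aligned to the (interpolated) map grid."""

    mask: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            raise InvalidParameterError("mask must be boolean")
        if not m.any():
            raise EmptyRoiError(f"ROI '{self.label}' selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RatioSet:
    """Dimensionless ROI metabolite ratios.

    Undefined ratios (denominator below floor) are NaN; ``defined`` is
    False in that case.  ``lac_bic`` always equals ``lac_pyr /
    bic_pyr`` when both come from the same sums.
    """

    lac_pyr: float
    bic_pyr: float
    lac_bic: float
    lac_total: float
    bic_total: float
    n_voxels: int
    n_masked: int = 0

    @property
    def defined(self) -> bool:
        return math.isfinite(self.lac_bic)


def ratio_set_from_sums(
    pyr: float, lac: float, bic: float, n_voxels: int, floor: float = 0.0,
    n_masked: int = 0,
) -> RatioSet:
    """Build a RatioSet from ROI sums, flooring small denominators."""

    def div(num: float, den: float) -> float:
        return num / den if den > floor and den > 0 else float("nan")

    total = pyr + lac + bic
    return RatioSet(
        lac_pyr=div(lac, pyr),
        bic_pyr=div(bic, pyr),
        lac_bic=div(lac, bic),
        lac_total=div(lac, total),
        bic_total=div(bic, total),
        n_voxels=n_voxels,
        n_masked=n_masked,
    )


def roi_ratios(
    maps: MetaboliteMapSet,
    mask: RoiMask,
    mode: str = "sum-ratio",
    floor_frac: float = 1e-3,
) -> RatioSet:
    """ROI metabolite ratios from reconstructed maps.

    ``mode='sum-ratio'`` (default): each ratio is the ratio of map sums
    over the ROI.  When the map set carries unclamped (``raw``) areas
    these are summed instead of the clamped display maps: clamping
    censors the negative half of the noise and would bias low-SNR ROI
    sums upward, whereas zero-mean noise largely cancels in a raw sum.
    ``mode='mean-ratio'``: mean over voxels of the per-voxel ratio,
    with voxels whose denominator falls below ``floor_frac`` x map
    maximum excluded (counted in ``n_masked``).
    """
    for name in ("pyr", "lac", "bic"):
        if name not in maps.maps:
            raise InvalidParameterError(f"maps lack a '{name}' channel")
    if maps.shape != mask.mask.shape:
        raise ShapeError(
            f"mask shape {mask.mask.shape} does not match maps {maps.shape}"
        )
    m = mask.mask
    source = maps.raw if maps.raw is not None else maps.maps
    pyr, lac, bic = source["pyr"], source["lac"], source["bic"]
    if mode == "sum-ratio":
        floor = floor_frac * max(float(pyr.max()), float(bic.max()), 0.0)
        return ratio_set_from_sums(
            float(pyr[m].sum()),
            float(lac[m].sum()),
            float(bic[m].sum()),
            n_voxels=mask.n_voxels,
            floor=floor,
        )
    if mode == "mean-ratio":
        floor_p = floor_frac * float(pyr.max())
        floor_b = floor_frac * float(bic.max())
        ok = m & (pyr > floor_p) & (bic > floor_b)
        n_masked = int(m.sum() - ok.sum())
        if not ok.any():
            raise EmptyRoiError("all ROI voxels fall below the denominator floor")
        tot = pyr + lac + bic
        return RatioSet(
            lac_pyr=float(np.mean(lac[ok] / pyr[ok])),
            bic_pyr=float(np.mean(bic[ok] / pyr[ok])),
            lac_bic=float(np.mean(lac[ok] / bic[ok])),
            lac_total=float(np.mean(lac[ok] / tot[ok])),
            bic_total=float(np.mean(bic[ok] / tot[ok])),
            n_voxels=int(ok.sum()),
            n_masked=n_masked,
        )
    raise InvalidParameterError(f"unknown mode {mode!r}")


def classify_response(pre: RatioSet, post: RatioSet) -> str:
    """Direction of the 48-hr Lac/Bic change.

    Returns 'increase', 'decrease', 'tie', or 'unclassifiable' when
    either ratio is undefined.  An increase marks a non-responder, a
    decrease a responder.
    """
    if not (pre.defined and post.defined):
        return "unclassifiable"
    d = post.lac_bic - pre.lac_bic
    if d > 0:
        return "increase"
    if d < 0:
        return "decrease"
    return "tie"


@dataclass(frozen=True)
class VolumeEstimate:
    """Voxel-counting volume: n_voxels x voxel volume."""

    volume_mm3: float
    n_voxels: int
    voxel_dims_mm: tuple[float, float, float]


def tumor_volume(
    mask_stack: Sequence[np.ndarray], voxel_dims_mm: tuple[float, float, float]
) -> VolumeEstimate:
    """Integrate enhanced voxels over slices times the slice thickness.

    ``voxel_dims_mm`` is (in-plane dy, in-plane dx, slice thickness).
    """
    if len(mask_stack) == 0:
        raise EmptyInputError("no slices")
    shapes = {np.asarray(s).shape for s in mask_stack}
    if len(shapes) > 1:
        raise ShapeError("slices have inconsistent shapes")
    dy, dx, dz = voxel_dims_mm
    if dy <= 0 or dx <= 0 or dz <= 0:
        raise InvalidParameterError("voxel dimensions must be > 0")
    n = int(sum(int(np.asarray(s, dtype=bool).sum()) for s in mask_stack))
    return VolumeEstimate(
        volume_mm3=n * dy * dx * dz, n_voxels=n, voxel_dims_mm=(dy, dx, dz)
    )


def growth_rate(vol_post: float, vol_pre: float) -> float:
    """48-hr growth rate: post-treatment over baseline tumor volume."""
    if vol_pre <= 0:
        raise UndefinedGrowthError("baseline volume must be > 0")
    return vol_post / vol_pre


def tumor_mask_from_enhancement(
    enhancement: np.ndarray, threshold_frac: float = 0.5
) -> RoiMask:
    """Synthetic Gd-enhancement segmentation: voxels above a fraction of
    the slice maximum (stand-in for the manual contrast-enhanced ROI)."""
    enh = np.asarray(enhancement, dtype=float)
    if enh.size == 0:
        raise EmptyInputError("empty enhancement map")
    mask = enh > threshold_frac * enh.max()
    return RoiMask(mask=mask, label="tumor")
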