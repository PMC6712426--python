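"""Seed-growing lesion segmentation and longitudinal volume summaries.

Hematoma (FLAIR-hypointense) and perihematomal edema (hyperintense) masks
are grown from user-placed seed voxels: a voxel joins the region when it is
connected to it (6- or 26-neighbourhood) and its intensity lies within a
tolerance of the running region mean.  The intracranial volume (ICV) is a
simple head-versus-background threshold closed morphologically.  Volumes are
voxel counts times the voxel volume, reported in ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class SegmentationParams:
    """One seed per target class plus growth controls.

    tolerance is the absolute intensity half-range accepted around the
    running region mean; connectivity selects face-only (6) or full (26)
    neighbourhoods; max_iter caps the number of growth sweeps.
    """

    seeds: list[tuple[tuple[int, int, int], str]] = field(default_factory=list)
    tolerance: float = 25.0
    connectivity: int = 26
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class RegionGrowResult:
    mask: np.ndarray
    iterations: int
    mean_intensity: float
    qc_flags: tuple[str, ...] = ()


def region_grow(image: np.ndarray, seed: tuple[int, int, int],
                tolerance: float, connectivity: int = 26,
                max_iter: int = 10_000,
                running_mean: bool = True) -> RegionGrowResult:
    """Grow a connected region of similar intensity from one seed voxel.

    Each sweep adds every not-yet-included neighbour of the current region
    whose intensity lies within ``tolerance`` of the region's reference
    intensity; with ``running_mean`` (default) the reference is the evolving
    region mean, otherwise the fixed seed intensity.  Sweeps are batch
    updates, so the result is deterministic for fixed inputs.  A mask that
    reaches the image border is flagged as a possible leak into background.
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    seed = tuple(int(c) for c in seed)
    if any(c < 0 or c >= n for c, n in zip(seed, image.shape)):
        raise ValueError(f"seed {seed} outside image bounds {image.shape}")
    structure = ndimage.generate_binary_structure(image.ndim,
                                                  1 if connectivity == 6 else image.ndim)
    mask = np.zeros(image.shape, dtype=bool)
    mask[seed] = True
    ref = float(image[seed])
    total = ref
    count = 1
    iterations = 0
    while iterations < max_iter:
        frontier = ndimage.binary_dilation(mask, structure) & ~mask
        accept = frontier & (np.abs(image - ref) <= tolerance)
        n_new = int(np.count_nonzero(accept))
        if n_new == 0:
            break
        mask |= accept
        iterations += 1
        if running_mean:
            total += float(image[accept].sum())
            count += n_new
            ref = total / count
    flags: tuple[str, ...] = ()
    border = np.zeros(image.shape, dtype=bool)
    for ax in range(image.ndim):
        sl = [slice(None)] * image.ndim
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if (mask & border).any():
        flags += ("mask_touches_border",)
    if iterations >= max_iter:
        flags += ("max_iter_reached",)
    return RegionGrowResult(mask=mask, iterations=iterations,
                            mean_intensity=float(image[mask].mean()),
                            qc_flags=flags)


def icv_mask(image: np.ndarray, closing_iter: int = 2) -> np.ndarray:
    """Head-versus-background mask: threshold, close, fill holes.

    The threshold sits halfway between the background floor and a robust
    head intensity (99th percentile), so both the hypointense hematoma and
    the hyperintense edema end up inside after hole filling.
    """
    thr = 0.5 * (float(image.min()) + float(np.percentile(image, 99)))
    mask = image > thr
    structure = ndimage.generate_binary_structure(image.ndim, 1)
    mask = ndimage.binary_closing(mask, structure, iterations=closing_iter)
    return ndimage.binary_fill_holes(mask)


def segment_phantom(image, params: SegmentationParams,
                    include_icv: bool = True) -> dict[str, RegionGrowResult | np.ndarray]:
    """Run seed growing for every seeded class (plus a thresholded ICV)."""
    data = image.get_fdata() if isinstance(image, nib.spatialimages.SpatialImage) \
        else np.asarray(image)
    out: dict[str, object] = {}
    for seed, cls in params.seeds:
        out[cls] = region_grow(data, seed, params.tolerance,
                               connectivity=params.connectivity,
                               max_iter=params.max_iter)
    if include_icv:
        out["icv"] = icv_mask(data)
    return out


def compute_volumes(masks: dict, voxel_mm: float | tuple[float, float, float],
                    animal: str | None = None, day: int | None = None) -> dict:
    """Voxel counts times voxel volume, in ml.

    ``masks`` maps class name to a boolean array or RegionGrowResult;
    ``voxel_mm`` is a scalar edge (isotropic) or per-axis tuple.
    """
    if np.isscalar(voxel_mm):
        vox_ml = float(voxel_mm) ** 3 / 1000.0
    else:
        vox_ml = float(np.prod(voxel_mm)) / 1000.0
    out = {"animal": animal, "day": day}
    for name, m in masks.items():
        arr = m.mask if isinstance(m, RegionGrowResult) else np.asarray(m)
        out[f"{name}_ml"] = float(np.count_nonzero(arr)) * vox_ml
    return out


def percent_change(series: pd.DataFrame, value_col: str,
                   baseline_day: int = 1, day_col: str = "day") -> pd.DataFrame:
    """Per-day percent reduction relative to a baseline day.

    Returns ``100 * (V_baseline - V_day) / V_baseline`` per day (positive =
    shrinkage).  Rows whose baseline is zero are flagged and get NaN.
    If several rows share a day (a cohort), day means are compared.
    """
    means = series.groupby(day_col)[value_col].mean()
    if baseline_day not in means.index:
        raise ValueError(f"baseline day {baseline_day} not present")
    v0 = means.loc[baseline_day]
    rows = []
    for day, v in means.items():
        undefined = v0 == 0
        rows.append({
            day_col: day,
            value_col: v,
            "pct_reduction": np.nan if undefined else 100.0 * (v0 - v) / v0,
            "qc_flags": "baseline_zero" if undefined else "",
        })
    return pd.DataFrame(rows)
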