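"""Circular-ROI / spherical-VOI voxel selection and statistics.

Voxel inclusion is by the strict centre rule: a voxel belongs to an ROI iff its
centre lies strictly inside the boundary.  This is deterministic, matches
common viewer behaviour, and makes selections translation-consistent (shifting
the centre by one voxel pitch shifts the selected index set by one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import EmptyROIError, GeometryError, ValidationError
from .grid import GridSpec
from .adc import ADCMap

__all__ = ["ROISpec", "ROIStats", "RepeatSeries", "ProfilePoint",
           "select_voxels", "roi_statistics", "shifted_roi_series"]


@dataclass(frozen=True)
class ROISpec:
    """A circle-in-plane ROI or spherical VOI, in world (mm) coordinates."""

    shape: str  # "circle" | "sphere"
    center: Tuple[float, float, float]
    diameter_mm: float
    plane: Optional[int] = None  # slice index, circles only

    def __post_init__(self):
        if self.shape not in ("circle", "sphere"):
            raise ValidationError(f"unknown ROI shape {self.shape!r}")
        if self.diameter_mm <= 0:
            raise ValidationError("ROI diameter must be > 0")


@dataclass(frozen=True)
class ROIStats:
    """Count, mean and sample SD of (valid) ADC values inside one ROI."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("ROIStats needs n >= 1")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n == 1 and self.sd != 0:
            raise ValidationError("sd must be 0 when n == 1")


@dataclass(frozen=True)
class RepeatSeries:
    """The same ROI measured across repeated acquisitions."""

    stats: Tuple[ROIStats, ...]

    def __post_init__(self):
        object.__setattr__(self, "stats", tuple(self.stats))
        if len(self.stats) < 1:
            raise ValidationError("RepeatSeries needs >= 1 repeats")

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.stats])

    @property
    def mu_r(self) -> float:
        """Mean of the repeat means."""
        return float(self.means.mean())

    @property
    def sigma_r(self) -> float:
        """Sample SD of the repeat means (needs >= 2 repeats)."""
        if len(self.stats) < 2:
            raise ValidationError("sigma_R needs >= 2 repeats")
        return float(self.means.std(ddof=1))


def _resolve_plane(grid: GridSpec, roi: ROISpec) -> int:
    if roi.plane is not None:
        if not 0 <= roi.plane < grid.shape[2]:
            raise GeometryError(f"plane {roi.plane} outside grid")
        return int(roi.plane)
    # nearest slice to the ROI centre's z coordinate
    return int(np.argmin(np.abs(grid.axis_centers(2) - roi.center[2])))


def select_voxels(grid: GridSpec, roi: ROISpec) -> np.ndarray:
    """Boolean voxel mask of the ROI on ``grid`` (strict centre-inside rule).

    Raises :class:`EmptyROIError` if no voxel centre falls inside the ROI.
    """
    r2 = (roi.diameter_mm / 2.0) ** 2
    x = grid.axis_centers(0)[:, None, None] - roi.center[0]
    y = grid.axis_centers(1)[None, :, None] - roi.center[1]
    mask = np.zeros(grid.shape, dtype=bool)
    if roi.shape == "circle":
        k = _resolve_plane(grid, roi)
        mask[:, :, k] = (x[..., 0] ** 2 + y[..., 0] ** 2) < r2
    else:
        z = grid.axis_centers(2)[None, None, :] - roi.center[2]
        mask = (x ** 2 + y ** 2 + z ** 2) < r2
    if not mask.any():
        raise EmptyROIError(
            f"{roi.shape} ROI (d={roi.diameter_mm} mm at {roi.center}) "
            "selects no voxels")
    return mask


def roi_statistics(adc_map: ADCMap, voxels: np.ndarray) -> ROIStats:
    """n / mean / sample-SD over the mask-valid voxels of the selection."""
    sel = np.asarray(voxels, dtype=bool) & adc_map.mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError("no valid voxels in ROI")
    vals = adc_map.values[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ROIStats(n=n, mean=float(vals.mean()), sd=sd)


@dataclass(frozen=True)
class ProfilePoint:
    """One entry of a shifted-ROI series."""

    distance_mm: float
    stats: ROIStats
    relative_pct: float  # 100 * (mean_d - mean_0) / mean_0


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def shifted_roi_series(adc_map: ADCMap, axis: str, step_mm: float, n_steps: int,
                       diameter_mm: float,
                       center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
                       plane: Optional[int] = None) -> List[ProfilePoint]:
    """ROI statistics at distances ``0, step, ..., n_steps*step`` along an axis.

    The value at each distance is reported relative to the distance-0 mean
    (``100 * (mu_d - mu_0) / mu_0``; exactly 0 at distance 0).  An ROI whose
    selection becomes empty (it left the grid) truncates the series with a
    warning rather than silently clipping.
    """
    if axis not in _AXIS_INDEX:
        raise ValidationError(f"axis must be one of {sorted(_AXIS_INDEX)}")
    if step_mm <= 0 or n_steps < 0:
        raise ValidationError("step_mm must be > 0 and n_steps >= 0")
    ax = _AXIS_INDEX[axis]
    points: List[ProfilePoint] = []
    mu0 = None
    for k in range(n_steps + 1):
        c = list(center)
        c[ax] += k * step_mm
        roi = ROISpec(shape="circle", center=tuple(c), diameter_mm=diameter_mm,
                      plane=plane)
        try:
            stats = roi_statistics(adc_map, select_voxels(adc_map.grid, roi))
        except EmptyROIError:
            warnings.warn(
                f"shifted ROI at {k * step_mm:.0f} mm leaves the grid; "
                f"series truncated after {len(points)} points", stacklevel=2)
            break
        if mu0 is None:
            mu0 = stats.mean
            rel = 0.0
        else:
            rel = 100.0 * (stats.mean - mu0) / mu0
        points.append(ProfilePoint(distance_mm=k * step_mm, stats=stats,
                                   relative_pct=rel))
    if not points:
        raise EmptyROIError("no shifted ROI fits the grid")
    return points
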