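"""Sphere-phantom partial-volume analyses.

Three studies on a phantom of spheres with known common true ADC:

* **scaling**: one VOI per sphere at 80 % of the sphere diameter (floored at a
  minimum resolvable size); relative error of each sphere's repeat-averaged
  mean ADC against the largest (reference) sphere.  Small spheres pick up
  partial-volume contamination from the surround, large ones do not.
* **concentric**: VOIs of decreasing diameter nested inside the reference
  sphere — a pure VOI-size effect with no contamination, expected flat.
* **differential same-size**: the sphere's 80 % VOI compared against an
  *identically sized* VOI centred in the reference sphere, cancelling the pure
  VOI-size effect so that what remains is partial volume alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .adc import ADCMap
from .exceptions import EmptyROIError, GeometryError, ValidationError
from .roi import ROISpec, ROIStats, RepeatSeries, roi_statistics, select_voxels
from .qc import cv_repeatability

__all__ = ["SphereLayout", "ScalingRow", "ConcentricRow", "DifferentialRow",
           "relative_error_pct", "scaling_analysis", "concentric_voi_analysis",
           "differential_same_size_analysis", "DEFAULT_MIN_VOI_MM"]

#: Smallest resolvable VOI diameter (mm): below this, 80 %-scaled VOIs are
#: floored because too few voxels sample them.
DEFAULT_MIN_VOI_MM = 10.0


@dataclass(frozen=True)
class SphereLayout:
    """Positions and diameters of the sphere inserts; reference = largest."""

    spheres: Tuple[Tuple[str, Tuple[float, float, float], float], ...]
    # each entry: (id, center mm, diameter mm)

    def __post_init__(self):
        object.__setattr__(self, "spheres", tuple(
            (str(i), tuple(float(v) for v in c), float(d))
            for i, c, d in self.spheres))
        diams = [d for _, _, d in self.spheres]
        if not diams:
            raise ValidationError("layout needs >= 1 sphere")
        if any(d <= 0 for d in diams):
            raise ValidationError("sphere diameters must be > 0")
        if len(set(diams)) != len(diams):
            raise ValidationError("sphere diameters must be unique")

    @property
    def reference(self) -> Tuple[str, Tuple[float, float, float], float]:
        return max(self.spheres, key=lambda s: s[2])

    @classmethod
    def from_scene(cls, scene) -> "SphereLayout":
        """Layout of every spherical primitive in a phantom scene."""
        entries = []
        for k, p in enumerate(scene.primitives):
            if hasattr(p, "diameter_mm") and not hasattr(p, "length_mm"):
                entries.append((f"sphere-{p.diameter_mm:g}mm", p.center,
                                p.diameter_mm))
        return cls(tuple(entries))


def relative_error_pct(mean: float, reference_mean: float) -> float:
    """``100 * (mean - reference) / reference`` — the tables' arithmetic."""
    if reference_mean == 0:
        raise ValidationError("reference mean must be non-zero")
    return 100.0 * (mean - reference_mean) / reference_mean


def voi_diameter(sphere_diameter: float, fraction: float,
                 min_voi_mm: float) -> float:
    """80 %-rule VOI diameter: rounded to whole mm (as VOI tools quantise),
    floored at the sampling limit and capped at the sphere diameter.

    For the standard sphere set this yields 30/22/18/14/10/10 mm for the
    37/28/22/17/13/10 mm spheres.
    """
    return min(max(round(fraction * sphere_diameter), min_voi_mm),
               sphere_diameter)


def _voi_repeat_stats(maps: Sequence[ADCMap], center, diameter) -> RepeatSeries:
    roi = ROISpec(shape="sphere", center=tuple(center), diameter_mm=diameter)
    voxels = select_voxels(maps[0].grid, roi)
    return RepeatSeries(tuple(roi_statistics(m, voxels) for m in maps))


@dataclass(frozen=True)
class ScalingRow:
    sphere_id: str
    sphere_diameter_mm: float
    voi_diameter_mm: float
    n_voxels: int
    mean_adc: float          # mean over repeats of the VOI means, mm^2/s
    relative_error_pct: float  # vs the reference sphere
    cv_pct: Optional[float]    # across repeats; None with a single map
    error: Optional[str] = None  # set when this sphere's VOI failed


@dataclass(frozen=True)
class ConcentricRow:
    voi_diameter_mm: float
    stats: ROIStats
    deviation_pct: float  # vs the largest VOI


@dataclass(frozen=True)
class DifferentialRow:
    reference_diameter_mm: float
    target_diameter_mm: float
    voi_diameter_mm: float
    n_voxels: int
    mean_adc_reference: float
    mean_adc_target: float
    abs_relative_error_pct: float


def scaling_analysis(maps: Sequence[ADCMap], layout: SphereLayout,
                     voi_fraction: float = 0.8,
                     min_voi_mm: float = DEFAULT_MIN_VOI_MM) -> List[ScalingRow]:
    """Per-sphere 80 %-VOI study: repeat-averaged mean ADC, relative error
    against the reference sphere, and CV across repeats.

    An empty VOI produces a row with ``error`` set; the other spheres are
    still analysed.
    """
    if not maps:
        raise ValidationError("need >= 1 ADC map")
    if not 0 < voi_fraction <= 1:
        raise ValidationError("voi_fraction must be in (0, 1]")
    ref_id, ref_center, ref_d = layout.reference
    ref_voi = voi_diameter(ref_d, voi_fraction, min_voi_mm)
    ref_rep = _voi_repeat_stats(maps, ref_center, ref_voi)
    rows: List[ScalingRow] = []
    for sid, center, d in sorted(layout.spheres, key=lambda s: -s[2]):
        voi_d = voi_diameter(d, voi_fraction, min_voi_mm)
        try:
            rep = _voi_repeat_stats(maps, center, voi_d)
        except EmptyROIError as exc:
            rows.append(ScalingRow(sid, d, voi_d, 0, float("nan"),
                                   float("nan"), None, error=str(exc)))
            continue
        cv = cv_repeatability(rep) if len(maps) > 1 else None
        rows.append(ScalingRow(
            sphere_id=sid, sphere_diameter_mm=d, voi_diameter_mm=voi_d,
            n_voxels=rep.stats[0].n, mean_adc=rep.mu_r,
            relative_error_pct=relative_error_pct(rep.mu_r, ref_rep.mu_r),
            cv_pct=cv))
    return rows


def concentric_voi_analysis(adc_map: ADCMap, layout: SphereLayout,
                            voi_diameters: Sequence[float]
                            ) -> List[ConcentricRow]:
    """Nested VOIs of decreasing size centred in the reference sphere.

    Deviations are relative to the largest VOI's mean.  A VOI larger than the
    reference sphere is rejected (it would not be concentric *inside* it).
    """
    _, center, ref_d = layout.reference
    diams = sorted(set(float(d) for d in voi_diameters), reverse=True)
    if not diams:
        raise ValidationError("need >= 1 VOI diameter")
    if diams[0] > ref_d:
        raise GeometryError(
            f"VOI {diams[0]} mm exceeds the {ref_d} mm reference sphere")
    rows: List[ConcentricRow] = []
    largest_mean = None
    for d in diams:
        stats = roi_statistics(adc_map, select_voxels(
            adc_map.grid, ROISpec(shape="sphere", center=center, diameter_mm=d)))
        if largest_mean is None:
            largest_mean = stats.mean
        rows.append(ConcentricRow(
            voi_diameter_mm=d, stats=stats,
            deviation_pct=relative_error_pct(stats.mean, largest_mean)))
    return rows


def differential_same_size_analysis(maps: Sequence[ADCMap],
                                    layout: SphereLayout,
                                    voi_fraction: float = 0.8,
                                    min_voi_mm: float = DEFAULT_MIN_VOI_MM
                                    ) -> List[DifferentialRow]:
    """Same-size differential partial-volume quantification.

    For every non-reference sphere, its (floored) 80 % VOI is measured in the
    sphere *and*, with identical diameter, centred in the reference sphere; the
    row reports both repeat-averaged means and ``|relative error|`` with the
    reference VOI as denominator.  Sharing the VOI size removes the pure
    VOI-size effect, isolating partial-volume contamination.
    """
    if not maps:
        raise ValidationError("need >= 1 ADC map")
    ref_id, ref_center, ref_d = layout.reference
    rows: List[DifferentialRow] = []
    for sid, center, d in sorted(layout.spheres, key=lambda s: -s[2]):
        if d == ref_d:
            continue
        voi_d = voi_diameter(d, voi_fraction, min_voi_mm)
        if voi_d > ref_d:
            raise GeometryError(
                f"VOI {voi_d} mm does not fit the reference sphere")
        target = _voi_repeat_stats(maps, center, voi_d)
        ref = _voi_repeat_stats(maps, ref_center, voi_d)
        rows.append(DifferentialRow(
            reference_diameter_mm=ref_d, target_diameter_mm=d,
            voi_diameter_mm=voi_d, n_voxels=target.stats[0].n,
            mean_adc_reference=ref.mu_r, mean_adc_target=target.mu_r,
            abs_relative_error_pct=abs(
                relative_error_pct(target.mu_r, ref.mu_r))))
    return rows
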