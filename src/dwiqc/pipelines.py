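"""End-to-end analysis pipelines tying the stages together.

These are the programmatic equivalents of chaining the CLI stages: simulate a
phantom, fit ADC maps, compute the QC report / spatial profiles / sphere
tables / reader-agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .adc import ADCMap, compute_adc_pair
from .agreement import AgreementResult, agreement_report, meaningful_change_range
from .qc import QCReport, QCThresholds, qc_report, spatial_profile, SpatialProfile
from .readerstudy import ReaderStudyConfig, simulate_reader_study
from .roi import ROISpec, RepeatSeries, roi_statistics, select_voxels, \
    shifted_roi_series
from .spheres import ScalingRow, ConcentricRow, DifferentialRow, SphereLayout, \
    scaling_analysis, concentric_voi_analysis, differential_same_size_analysis
from .synth import BiasField, DWISeries, icewater_scene, rasterize_scene, \
    sphere_phantom_scene, synthesize_dwi

#: Ice-water QC protocol b-values (s/mm²).
QC_B_VALUES = (0.0, 100.0, 600.0, 800.0)
#: Clinical / sphere-phantom protocol b-values (s/mm²).
CLINICAL_B_VALUES = (50.0, 1000.0)


@dataclass
class IcewaterQCResult:
    series: List[DWISeries]
    maps_by_pair: Dict[Tuple[float, float], List[ADCMap]]
    repeats_by_pair: Dict[Tuple[float, float], RepeatSeries]
    report: Optional[QCReport]  # None with a single repeat (no repeatability)


def run_icewater_qc(seed: Optional[int] = 0, noise_sd: float = 0.0,
                    n_repeats: int = 4, bias: Optional[BiasField] = None,
                    b_values: Sequence[float] = QC_B_VALUES,
                    roi_diameter_mm: float = 25.0,
                    thresholds: Optional[QCThresholds] = None,
                    supersample: int = 5) -> IcewaterQCResult:
    """Simulate the ice-water phantom protocol and produce the QC report.

    Four repeated acquisitions (default) at b = 0/100/600/800 s/mm², ADC maps
    from each b0–bX pair, a centred circular ROI, and the six QC metrics judged
    against the claim thresholds.
    """
    scene = icewater_scene()
    raster = rasterize_scene(scene, supersample=supersample)
    series = synthesize_dwi(raster, b_values, bias=bias, noise_sd=noise_sd,
                            n_repeats=n_repeats, seed=seed)
    grid = scene.grid
    roi = ROISpec(shape="circle", center=(0.0, 0.0, 0.0),
                  diameter_mm=roi_diameter_mm, plane=grid.shape[2] // 2)
    voxels = select_voxels(grid, roi)

    maps_by_pair: Dict[Tuple[float, float], List[ADCMap]] = {}
    repeats_by_pair: Dict[Tuple[float, float], RepeatSeries] = {}
    b0 = b_values[0]
    for b_high in b_values[1:]:
        pair = (float(b0), float(b_high))
        maps = [compute_adc_pair(s, *pair) for s in series]
        maps_by_pair[pair] = maps
        repeats_by_pair[pair] = RepeatSeries(
            tuple(roi_statistics(m, voxels) for m in maps))

    b0_repeats = [s.volume(b0) for s in series]
    report = None
    if n_repeats >= 2:
        report = qc_report(repeats_by_pair, b0_repeats=b0_repeats,
                           roi_voxels=voxels, thresholds=thresholds)
    return IcewaterQCResult(series=series, maps_by_pair=maps_by_pair,
                            repeats_by_pair=repeats_by_pair, report=report)


def run_spatial_profile(adc_map: ADCMap, axis: str = "y", step_mm: float = 20.0,
                        n_steps: int = 4, diameter_mm: float = 22.0
                        ) -> SpatialProfile:
    """Shifted-ROI spatial bias profile of an ADC map, with Pearson r."""
    points = shifted_roi_series(adc_map, axis=axis, step_mm=step_mm,
                                n_steps=n_steps, diameter_mm=diameter_mm,
                                plane=adc_map.grid.shape[2] // 2)
    return spatial_profile(points, axis=axis)


@dataclass
class SphereStudyResult:
    layout: SphereLayout
    maps: List[ADCMap]
    scaling: List[ScalingRow]
    concentric: List[ConcentricRow]
    differential: List[DifferentialRow]


def run_sphere_study(seed: Optional[int] = 0, noise_sd: float = 0.0,
                     n_repeats: int = 4,
                     b_values: Sequence[float] = CLINICAL_B_VALUES,
                     voi_fraction: float = 0.8,
                     background_s0: float = 100.0,
                     background_adc: float = 0.3e-3,
                     concentric_diameters: Sequence[float] = (
                         30.0, 26.0, 22.0, 18.0, 14.0, 10.0),
                     voi_offset_mm: Tuple[float, float, float] = (0.0, 0.0, 2.5),
                     supersample: int = 5) -> SphereStudyResult:
    """Simulate the six-sphere phantom over repeated days and run all three
    partial-volume analyses.

    ``voi_offset_mm`` displaces every analysis VOI from the true sphere centre
    (default: half a slice thickness along z).  Hand-placed VOIs are centred
    visually on the slice stack, so a placement uncertainty of about half the
    slice spacing is inherent to the measurement; with mathematically perfect
    centring the 80 % VOIs of the larger spheres would touch no boundary voxel
    at all and the partial-volume effect under study would vanish.
    """
    scene = sphere_phantom_scene(background_s0=background_s0,
                                 background_adc=background_adc)
    true_layout = SphereLayout.from_scene(scene)
    layout = SphereLayout(tuple(
        (sid, tuple(c + o for c, o in zip(center, voi_offset_mm)), d)
        for sid, center, d in true_layout.spheres))
    raster = rasterize_scene(scene, supersample=supersample)
    series = synthesize_dwi(raster, b_values, noise_sd=noise_sd,
                            n_repeats=n_repeats, seed=seed)
    maps = [compute_adc_pair(s, b_values[0], b_values[-1]) for s in series]
    return SphereStudyResult(
        layout=layout, maps=maps,
        scaling=scaling_analysis(maps, layout, voi_fraction=voi_fraction),
        # the concentric (pure VOI-size) study requires a clean interior, so it
        # uses the true sphere centre rather than the offset VOI placement
        concentric=concentric_voi_analysis(maps[0], true_layout,
                                           concentric_diameters),
        differential=differential_same_size_analysis(
            maps, layout, voi_fraction=voi_fraction))


@dataclass
class ReaderStudyResult:
    table: pd.DataFrame
    inter_reader: AgreementResult
    intra_reader: Dict[int, AgreementResult]
    meaningful_change: Optional[object]


def run_reader_study(config: Optional[ReaderStudyConfig] = None,
                     seed: Optional[int] = None) -> ReaderStudyResult:
    """Simulate the two-reader node study and compute all agreement statistics.

    The meaningful-change range is derived from reader 1's intra-observer
    relative limits of agreement.
    """
    if config is None:
        config = ReaderStudyConfig(seed=0 if seed is None else int(seed))
    elif seed is not None:
        config = ReaderStudyConfig(**{**config.__dict__, "seed": int(seed)})
    table = simulate_reader_study(config)
    inter = agreement_report(table, compare="readers", scale="relative")
    intra = {r: agreement_report(table, compare="sessions", scale="relative",
                                 reader=r) for r in (1, 2)}
    try:
        mcr = meaningful_change_range((intra[1].loa_low, intra[1].loa_high))
    except Exception:
        mcr = None
    return ReaderStudyResult(table=table, inter_reader=inter,
                             intra_reader=intra, meaningful_change=mcr)
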