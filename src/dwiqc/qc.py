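"""QIBA-style quality-control metrics for ice-water phantom ADC data.

Implements the six standard QC metrics for a 0 degC ice-water phantom —
repeatability (CV_R, RC_R), accuracy (ADC bias against the known true value
1.1e-3 mm²/s), precision (within-ROI noise estimate), b-value dependence and
temporal SNR — plus the spatial-bias profile analysis with Pearson
correlations.  Sample (n−1) standard deviations are used throughout; metric
formulas are implemented literally (no SD-estimator bias correction), so e.g.
``RC_R`` is exactly ``2.77 * sigma_R``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedSNRError, ValidationError
from .roi import ProfilePoint, ROIStats, RepeatSeries
from .synth import ICE_WATER_ADC

__all__ = [
    "QCThresholds", "PairMetrics", "QCReport", "SpatialProfile",
    "cv_repeatability", "repeatability_coefficient", "adc_bias_estimate",
    "adc_noise_estimate", "b_value_dependence", "snr_ndyn", "qc_report",
    "pearson", "pearson_ci", "spatial_profile",
]

#: Multiplier turning sigma_R into a repeatability coefficient, as conventionally
#: printed (2.77, not 1.96*sqrt(2)).
RC_FACTOR = 2.77


# ---------------------------------------------------------------------------
# The six metrics
# ---------------------------------------------------------------------------

def cv_repeatability(rep: RepeatSeries) -> float:
    """Coefficient of variation of repeated ROI means: ``100 * sigma_R / mu_R`` (%)."""
    if rep.mu_r <= 0:
        raise ValidationError("CV_R needs mu_R > 0")
    return 100.0 * rep.sigma_r / rep.mu_r


def repeatability_coefficient(rep: RepeatSeries) -> float:
    """Repeatability coefficient ``RC_R = 2.77 * sigma_R`` (mm²/s)."""
    return RC_FACTOR * rep.sigma_r


def adc_bias_estimate(mean_adc: float, dc_true: float = ICE_WATER_ADC
                      ) -> Tuple[float, float]:
    """ADC bias against the reference value: ``(mu - DC_true, 100*(mu-DC_true)/DC_true)``."""
    if dc_true <= 0:
        raise ValidationError("DC_true must be > 0")
    absolute = mean_adc - dc_true
    return absolute, 100.0 * absolute / dc_true


def adc_noise_estimate(stats: ROIStats) -> float:
    """Within-ROI spatial noise estimate: ``100 * sigma / mu`` (%)."""
    if stats.mean <= 0:
        raise ValidationError("noise estimate needs mu > 0")
    return 100.0 * stats.sd / stats.mean


def b_value_dependence(adc_mean_b1: float, adc_mean_b2: float) -> float:
    """b-value dependence ``100 * |(ADC_b2 - ADC_b1) / ADC_b1|`` (%).

    Not symmetric: the first argument is the denominator (conventionally the
    lower-b map, e.g. ADC(b0,b600) against ADC(b0,b800)).
    """
    if adc_mean_b1 <= 0:
        raise ValidationError("b-value dependence needs ADC_b1 > 0")
    return 100.0 * abs((adc_mean_b2 - adc_mean_b1) / adc_mean_b1)


def snr_ndyn(b0_repeats: Sequence[np.ndarray], roi_voxels: np.ndarray) -> float:
    """Temporal SNR from repeated b=0 volumes over an ROI.

    The signal image is the voxelwise temporal mean across repeats and the
    temporal noise image the voxelwise sample SD; both are spatially averaged
    over the ROI before dividing.  Identical repeats (zero noise image) raise
    :class:`UndefinedSNRError` rather than returning infinity.
    """
    if len(b0_repeats) < 2:
        raise ValidationError("SNR_nDyn needs >= 2 repeats")
    stack = np.stack([np.asarray(v, dtype=float) for v in b0_repeats])
    sel = np.asarray(roi_voxels, dtype=bool)
    if not sel.any():
        raise ValidationError("empty ROI for SNR_nDyn")
    signal = stack.mean(axis=0)[sel].mean()
    noise = stack.std(axis=0, ddof=1)[sel].mean()
    if noise == 0:
        raise UndefinedSNRError("temporal noise image is identically zero")
    return float(signal / noise)


# ---------------------------------------------------------------------------
# Pearson correlation (with brute-force-verifiable product-moment formula)
# ---------------------------------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson needs two equal-length 1-D sequences")
    if x.size < 3:
        raise ValidationError("pearson needs >= 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = (dx * dx).sum()
    syy = (dy * dy).sum()
    if sxx == 0 or syy == 0:
        raise ValidationError("pearson is undefined for zero-variance input")
    return float((dx * dy).sum() / np.sqrt(sxx * syy))


def pearson_ci(r: float, n: int, confidence: float = 0.95
               ) -> Tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if n < 4:
        raise ValidationError("Fisher-z CI needs n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    half = sps.norm.ppf(0.5 + confidence / 2.0) * se
    return float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass(frozen=True)
class SpatialProfile:
    """A shifted-ROI bias profile along one axis with its Pearson correlation."""

    axis: str
    distances_cm: Tuple[float, ...]
    relative_pct: Tuple[float, ...]
    pearson_r: float
    pearson_ci95: Tuple[float, float]

    def __post_init__(self):
        if self.distances_cm[0] != 0.0 or self.relative_pct[0] != 0.0:
            raise ValidationError("profile must start at (0 cm, 0 %)")
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValidationError("Pearson r out of [-1, 1]")


def spatial_profile(points: Sequence[ProfilePoint], axis: str) -> SpatialProfile:
    """Summarise a shifted-ROI series as a distance-vs-error profile."""
    d_cm = tuple(p.distance_mm / 10.0 for p in points)
    rel = tuple(p.relative_pct for p in points)
    r = pearson(d_cm, rel)
    return SpatialProfile(axis=axis, distances_cm=d_cm, relative_pct=rel,
                          pearson_r=r, pearson_ci95=pearson_ci(r, len(points)))


# ---------------------------------------------------------------------------
# Thresholds and report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Claim limits a QC run is judged against (strict inequalities).

    Defaults are the published claims for an ice-water phantom: CV_R < 1.5 %,
    RC_R < 1.5e-5 mm²/s, |bias| < 3.6 %, noise < 2 %, b-value dependence < 2 %,
    SNR >= 50, with DC_true = 1.1e-3 mm²/s for 0 degC water.
    """

    cv_max: float = 1.5
    rc_max: float = 1.5e-5
    bias_max: float = 3.6
    noise_max: float = 2.0
    bdep_max: float = 2.0
    snr_min: float = 50.0
    dc_true: float = ICE_WATER_ADC

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValidationError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class PairMetrics:
    """The per-b-pair QC metrics and their pass flags."""

    b_pair: Tuple[float, float]
    cv_r: float
    rc_r: float
    bias_abs: float
    bias_pct: float
    noise_pct: float
    passes: Dict[str, bool]


@dataclass(frozen=True)
class QCReport:
    """Full QC outcome: per-pair metrics, b-dependence, SNR, overall verdict."""

    pairs: Tuple[PairMetrics, ...]
    b_dependence_pct: Optional[float]
    b_dependence_pass: Optional[bool]
    snr: Optional[float]
    snr_pass: Optional[bool]  # None when SNR is undefined (noiseless data)
    thresholds: QCThresholds

    @property
    def all_pass(self) -> bool:
        ok = all(all(p.passes.values()) for p in self.pairs)
        if self.b_dependence_pass is not None:
            ok = ok and self.b_dependence_pass
        if self.snr_pass is not None:
            ok = ok and self.snr_pass
        return ok

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {"b_pair": list(p.b_pair), "cv_r_pct": p.cv_r,
                 "rc_r_mm2_s": p.rc_r, "bias_mm2_s": p.bias_abs,
                 "bias_pct": p.bias_pct, "noise_pct": p.noise_pct,
                 "passes": dict(p.passes)}
                for p in self.pairs],
            "b_dependence_pct": self.b_dependence_pct,
            "b_dependence_pass": self.b_dependence_pass,
            "snr_ndyn": self.snr,
            "snr_pass": self.snr_pass,
            "snr_undefined": self.snr is None,
            "all_pass": self.all_pass,
            "thresholds": dict(self.thresholds.__dict__),
        }


def qc_report(repeats_by_pair: Dict[Tuple[float, float], RepeatSeries],
              b0_repeats: Optional[Sequence[np.ndarray]] = None,
              roi_voxels: Optional[np.ndarray] = None,
              thresholds: Optional[QCThresholds] = None,
              bdep_pairs: Tuple[Tuple[float, float], Tuple[float, float]] =
              ((0.0, 600.0), (0.0, 800.0))) -> QCReport:
    """Assemble the full QC report and judge every metric against its claim.

    ``repeats_by_pair`` maps each b-pair to the ROI statistics of the repeated
    acquisitions.  The noise estimate per pair is the mean over repeats of the
    within-ROI ``100*sigma/mu``.  b-value dependence compares the repeat-mean
    ADCs of ``bdep_pairs`` (lower-b map is the denominator) when both are
    present.  All threshold comparisons are strict (boundary equality fails);
    SNR uses ``>=``.
    """
    thr = thresholds or QCThresholds()
    pairs: List[PairMetrics] = []
    for b_pair in sorted(repeats_by_pair):
        rep = repeats_by_pair[b_pair]
        cv = cv_repeatability(rep)
        rc = repeatability_coefficient(rep)
        bias_abs, bias_pct = adc_bias_estimate(rep.mu_r, thr.dc_true)
        noise = float(np.mean([adc_noise_estimate(s) for s in rep.stats]))
        passes = {
            "cv_r": cv < thr.cv_max,
            "rc_r": rc < thr.rc_max,
            "bias": abs(bias_pct) < thr.bias_max,
            "noise": noise < thr.noise_max,
        }
        pairs.append(PairMetrics(b_pair=b_pair, cv_r=cv, rc_r=rc,
                                 bias_abs=bias_abs, bias_pct=bias_pct,
                                 noise_pct=noise, passes=passes))

    bdep = bdep_pass = None
    lo, hi = bdep_pairs
    if lo in repeats_by_pair and hi in repeats_by_pair:
        bdep = b_value_dependence(repeats_by_pair[lo].mu_r,
                                  repeats_by_pair[hi].mu_r)
        bdep_pass = bdep < thr.bdep_max

    snr = snr_pass = None
    if b0_repeats is not None and roi_voxels is not None:
        try:
            snr = snr_ndyn(b0_repeats, roi_voxels)
            snr_pass = snr >= thr.snr_min
        except UndefinedSNRError:
            snr = snr_pass = None  # noiseless data: flagged, not failed

    return QCReport(pairs=tuple(pairs), b_dependence_pct=bdep,
                    b_dependence_pass=bdep_pass, snr=snr, snr_pass=snr_pass,
                    thresholds=thr)
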