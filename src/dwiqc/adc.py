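"""ADC map computation from diffusion-weighted series.

The apparent diffusion coefficient at a voxel follows from the
mono-exponential decay ``S(b) = S0 * exp(-b * ADC)``:

* two-point closed form: ``ADC = ln(S(b_low) / S(b_high)) / (b_high - b_low)``;
* multi-b log-linear fit: ADC is minus the OLS slope of ``ln S`` on ``b``.

As scanner consoles do, voxels whose signal falls at or below a configurable
floor are masked invalid rather than producing infinities or being zero-filled;
masked voxels are excluded from every downstream ROI statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import ValidationError
from .grid import GridSpec
from .synth import DWISeries

__all__ = ["ADCMap", "compute_adc_pair", "compute_adc_loglinear"]


@dataclass(frozen=True)
class ADCMap:
    """3-D ADC values (mm²/s) with a validity mask.

    ``values`` is NaN wherever ``mask`` is False; ``b_values`` records the
    b-pair (or subset) that produced the map.
    """

    values: np.ndarray
    mask: np.ndarray
    b_values: Tuple[float, ...]
    grid: GridSpec

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.shape != self.grid.shape or mask.shape != self.grid.shape:
            raise ValidationError("ADC map shape does not match grid")
        b = tuple(float(v) for v in self.b_values)
        if len(b) < 2 or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValidationError("ADC map needs >= 2 strictly increasing b-values")
        values = values.copy()
        values[~mask] = np.nan
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "b_values", b)

    @property
    def b_low(self) -> float:
        return self.b_values[0]

    @property
    def b_high(self) -> float:
        return self.b_values[-1]

    @classmethod
    def constant(cls, grid: GridSpec, value: float,
                 b_values: Tuple[float, float] = (0.0, 800.0)) -> "ADCMap":
        """Uniform map helper (used heavily in tests and table replays)."""
        return cls(np.full(grid.shape, value), np.ones(grid.shape, bool),
                   b_values, grid)


def compute_adc_pair(series: DWISeries, b_low: float, b_high: float,
                     signal_floor: float = 0.0) -> ADCMap:
    """Two-b-value ADC map.

    A voxel is valid iff both signals exceed ``signal_floor`` (default 0, i.e.
    all strictly positive signals are used).
    """
    if signal_floor < 0:
        raise ValidationError("signal_floor must be >= 0")
    if b_high <= b_low:
        raise ValidationError(f"need b_high > b_low, got ({b_low}, {b_high})")
    s_low = series.volume(b_low)
    s_high = series.volume(b_high)
    mask = (s_low > signal_floor) & (s_high > signal_floor)
    values = np.full(series.grid.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[mask] = np.log(s_low[mask] / s_high[mask]) / (b_high - b_low)
    return ADCMap(values=values, mask=mask, b_values=(b_low, b_high),
                  grid=series.grid)


def compute_adc_loglinear(series: DWISeries,
                          b_subset: Optional[Sequence[float]] = None,
                          signal_floor: float = 0.0) -> ADCMap:
    """Multi-b ADC map: minus the per-voxel OLS slope of ``ln S`` versus b.

    With exactly two b-values this reduces to :func:`compute_adc_pair` bit for
    bit.  A voxel is valid iff at least two of its b-points clear the signal
    floor; the fit at each voxel uses only that voxel's valid points.
    """
    if signal_floor < 0:
        raise ValidationError("signal_floor must be >= 0")
    b = tuple(float(v) for v in (b_subset if b_subset is not None
                                 else series.b_values))
    if len(b) < 2:
        raise ValidationError("need >= 2 b-values for a log-linear fit")
    if len(b) == 2:
        return compute_adc_pair(series, b[0], b[1], signal_floor)

    signals = np.stack([series.volume(v) for v in b], axis=-1)
    w = (signals > signal_floor).astype(float)
    n_valid = w.sum(axis=-1)
    mask = n_valid >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(w > 0, np.log(np.where(signals > 0, signals, 1.0)), 0.0)
        barr = np.asarray(b)
        sw = np.where(n_valid > 0, n_valid, 1.0)
        b_bar = (w * barr).sum(axis=-1) / sw
        y_bar = (w * logs).sum(axis=-1) / sw
        db = barr - b_bar[..., None]
        sxx = (w * db ** 2).sum(axis=-1)
        sxy = (w * db * (logs - y_bar[..., None])).sum(axis=-1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    mask = mask & (sxx > 0)
    values = np.where(mask, -slope, np.nan)
    return ADCMap(values=values, mask=mask, b_values=b, grid=series.grid)
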