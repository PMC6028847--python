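"""Inter- and intra-observer agreement statistics for reader measurement tables.

Bland-Altman bias and limits of agreement (absolute mm²/s or relative %, with
the pair mean as relative denominator), a tie-aware exact Wilcoxon signed-rank
test, and the log-symmetric meaningful-change range derived from intra-observer
limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateTestError, ValidationError

__all__ = ["AgreementResult", "MeaningfulChangeRange", "paired_differences",
           "bland_altman", "wilcoxon_signed_rank", "meaningful_change_range",
           "agreement_report", "LOA_FACTOR"]

#: Limits of agreement are bias +/- 1.96 * SD of the paired differences.
LOA_FACTOR = 1.96


# ---------------------------------------------------------------------------
# Pairing and Bland-Altman
# ---------------------------------------------------------------------------

def paired_differences(table: pd.DataFrame, compare: str = "readers",
                       scale: str = "relative", value_col: str = "mean_adc",
                       reader: Optional[int] = None
                       ) -> Tuple[np.ndarray, int]:
    """Paired differences from a reader-measurement table.

    ``compare="readers"`` pairs reader 1 against reader 2 per (subject, node),
    each reader represented by the mean of their sessions; ``"sessions"`` pairs
    session 1 against session 2 per (subject, node, reader) — restricted to one
    reader if ``reader`` is given.  Differences are first − second; relative
    differences use the pair mean as denominator
    (``100 * (a − b) / ((a + b) / 2)``).  Units missing either member are
    dropped; the count of dropped units is returned alongside.
    """
    if compare not in ("readers", "sessions"):
        raise ValidationError("compare must be 'readers' or 'sessions'")
    if scale not in ("absolute", "relative"):
        raise ValidationError("scale must be 'absolute' or 'relative'")
    df = table.copy()
    if compare == "readers":
        df = df.groupby(["subject", "node", "reader"], as_index=False)[
            value_col].mean()
        wide = df.pivot(index=["subject", "node"], columns="reader",
                        values=value_col)
        first, second = 1, 2
    else:
        if reader is not None:
            df = df[df["reader"] == reader]
        wide = df.pivot(index=["subject", "node", "reader"], columns="session",
                        values=value_col)
        first, second = 1, 2
    for col in (first, second):
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide[[first, second]].dropna()
    n_dropped = len(wide) - len(complete)
    if complete.empty:
        raise ValidationError("no complete pairs to compare")
    a = complete[first].to_numpy(dtype=float)
    b = complete[second].to_numpy(dtype=float)
    if scale == "absolute":
        return a - b, n_dropped
    return 100.0 * (a - b) / ((a + b) / 2.0), n_dropped


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of a set of paired differences."""

    scale: str
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    wilcoxon_statistic: Optional[float] = None
    wilcoxon_p: Optional[float] = None
    n_dropped: int = 0

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValidationError("LoA must bracket the bias")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def bland_altman(differences: Sequence[float], scale: str = "relative",
                 n_dropped: int = 0) -> AgreementResult:
    """Bias (mean difference) and limits of agreement ``bias ± 1.96·SD``."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValidationError("Bland-Altman needs >= 2 paired differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(scale=scale, n=int(d.size), bias=bias, sd_diff=sd,
                           loa_low=bias - LOA_FACTOR * sd,
                           loa_high=bias + LOA_FACTOR * sd,
                           n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (tie-aware exact null, n <= 25)
# ---------------------------------------------------------------------------

def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by dynamic programming over the 2^n sign patterns.

    Ranks may be mid-ranks (half-integers); doubling makes them integers so the
    distribution of the positive-rank sum is a subset-sum count.
    """
    t = np.rint(2.0 * ranks).astype(int)
    total = int(t.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for ti in t:
        counts[ti:] += counts[:total + 1 - ti].copy()
    n_patterns = 2.0 ** len(t)
    w2 = 2.0 * w_plus
    lo = counts[: int(math.floor(w2 + 0.5)) + 1].sum()  # P(W <= w)
    hi = counts[int(math.ceil(w2 - 0.5)):].sum()        # P(W >= w)
    return min(1.0, 2.0 * min(lo, hi) / n_patterns)


def wilcoxon_signed_rank(values: Sequence[float],
                         other: Optional[Sequence[float]] = None,
                         exact_max_n: int = 25) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on differences (or on two paired samples).

    Zero differences are dropped; ties are mid-ranked.  The null distribution
    is enumerated exactly for ``n <= exact_max_n`` and approximated normally
    (with tie and continuity corrections) above.  Returns ``(W+, p)``.
    """
    d = np.asarray(values, dtype=float)
    if other is not None:
        d = d - np.asarray(other, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n < 5:
        raise ValidationError(
            f"only {n} non-zero differences; need >= 5 for a meaningful test")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        # mid-rank tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        delta = w_plus - mean
        z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_plus, p


# ---------------------------------------------------------------------------
# Meaningful-change range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeaningfulChangeRange:
    """Asymmetric percent range outside which a longitudinal change is meaningful.

    Log-symmetric by construction: ``ln(1 + upper/100) = -ln(1 + lower/100)``.
    """

    lower_pct: float
    upper_pct: float
    method: str

    def __post_init__(self):
        if not (self.lower_pct < 0 < self.upper_pct):
            raise ValidationError("range must satisfy lower < 0 < upper")
        if abs(math.log1p(self.upper_pct / 100.0)
               + math.log1p(self.lower_pct / 100.0)) > 1e-9:
            raise ValidationError("range is not log-symmetric")


def meaningful_change_range(loa: Tuple[float, float]) -> MeaningfulChangeRange:
    """Meaningful-change range from intra-observer relative limits of agreement.

    The LoA half-width ``h`` (%) — the mean of |LoA low| and |LoA high| — is the
    repeatability of a *single* measurement; a change involves two, hence the
    ``sqrt(2)`` scaling.  Treating ``c = sqrt(2) * h / 100`` as a symmetric
    limit on the log scale gives the asymmetric percent range
    ``[100*(e^-c - 1), 100*(e^c - 1)]``.  The reconstruction is recorded in the
    method label.
    """
    h = (abs(loa[0]) + abs(loa[1])) / 2.0
    if h <= 0:
        raise ValidationError("LoA half-width must be > 0")
    c = math.sqrt(2.0) * h / 100.0
    return MeaningfulChangeRange(
        lower_pct=100.0 * (math.exp(-c) - 1.0),
        upper_pct=100.0 * (math.exp(c) - 1.0),
        method="log-symmetric sqrt(2)-scaled LoA half-width (reconstruction)")


# ---------------------------------------------------------------------------
# Convenience report
# ---------------------------------------------------------------------------

def agreement_report(table: pd.DataFrame, compare: str = "readers",
                     scale: str = "relative", value_col: str = "mean_adc",
                     reader: Optional[int] = None) -> AgreementResult:
    """Bland-Altman + Wilcoxon in one call on a reader-measurement table."""
    diffs, n_dropped = paired_differences(table, compare=compare, scale=scale,
                                          value_col=value_col, reader=reader)
    result = bland_altman(diffs, scale=scale, n_dropped=n_dropped)
    try:
        stat, p = wilcoxon_signed_rank(diffs)
    except (DegenerateTestError, ValidationError):
        stat = p = None
    return AgreementResult(scale=result.scale, n=result.n, bias=result.bias,
                           sd_diff=result.sd_diff, loa_low=result.loa_low,
                           loa_high=result.loa_high, wilcoxon_statistic=stat,
                           wilcoxon_p=p, n_dropped=n_dropped)
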