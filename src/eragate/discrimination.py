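"""Discrimination-factor (DF) statistics for single-nucleotide specificity.

DF compares the fluorescence produced by a perfectly matched (PM) activator
with that of a single-base-mismatched (MM) activator at a chosen time:

    DF = (F_PM - background) / (F_MM - background)

A mismatched condition indistinguishable from background (denominator below
an epsilon guard) yields an infinite DF, which is surfaced explicitly rather
than clipped.  Replicate DFs are summarized by their median with infinities
excluded (and counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import FluorescenceSeries

__all__ = ["DFResult", "discrimination_factor_at", "df_timecourse",
           "df_at_20min", "median_df", "fold_change"]


@dataclass
class DFResult:
    df: float
    time_s: float
    f_pm: float = math.nan
    f_mm: float = math.nan
    f_bg: float = math.nan
    infinite: bool = False
    replicate_dfs: list[float] = field(default_factory=list)
    median_df: float | None = None
    n_infinite_excluded: int = 0


def _value_at(series_or_scalar, t: float) -> float:
    if isinstance(series_or_scalar, FluorescenceSeries):
        return series_or_scalar.at(t)
    return float(series_or_scalar)


def discrimination_factor_at(pm: FluorescenceSeries, mm: FluorescenceSeries,
                             bg, t: float, epsilon_au: float = 0.0) -> DFResult:
    """DF at time t; series on different grids are linearly interpolated.

    ``bg`` may be a matched background series or a scalar.  When
    F_MM - F_bg <= epsilon_au the result carries df = +inf with the
    ``infinite`` flag set (mismatch indistinguishable from background).
    """
    f_pm = _value_at(pm, t)
    f_mm = _value_at(mm, t)
    f_bg = _value_at(bg, t)
    denom = f_mm - f_bg
    if denom <= epsilon_au:
        return DFResult(df=math.inf, time_s=t, f_pm=f_pm, f_mm=f_mm, f_bg=f_bg,
                        infinite=True)
    return DFResult(df=(f_pm - f_bg) / denom, time_s=t,
                    f_pm=f_pm, f_mm=f_mm, f_bg=f_bg)


def df_timecourse(pm: FluorescenceSeries, mm: FluorescenceSeries, bg,
                  epsilon_au: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """DF at every time of the PM grid; guarded points are +inf.

    Returns (times, df) arrays.  The conventional reporting time is 20 min
    (1200 s).
    """
    times = pm.times
    out = np.empty_like(times)
    for i, t in enumerate(times):
        out[i] = discrimination_factor_at(pm, mm, bg, float(t), epsilon_au).df
    return times, out


def df_at_20min(pm: FluorescenceSeries, mm: FluorescenceSeries, bg,
                epsilon_au: float = 0.0) -> DFResult:
    return discrimination_factor_at(pm, mm, bg, 1200.0, epsilon_au)


def median_df(replicate_triplets, t: float, epsilon_au: float = 0.0) -> DFResult:
    """Median DF across replicate (pm, mm, bg) triplets at time t.

    Infinite replicate DFs are excluded from the median and counted; if every
    replicate is infinite the sentinel (df = +inf, flagged) is returned.
    """
    triplets = list(replicate_triplets)
    if not triplets:
        raise ValueError("need at least one replicate triplet")
    dfs = [discrimination_factor_at(pm, mm, bg, t, epsilon_au).df
           for pm, mm, bg in triplets]
    finite = [d for d in dfs if math.isfinite(d)]
    n_inf = len(dfs) - len(finite)
    if not finite:
        return DFResult(df=math.inf, time_s=t, infinite=True,
                        replicate_dfs=dfs, median_df=math.inf,
                        n_infinite_excluded=n_inf)
    med = float(np.median(finite))
    return DFResult(df=med, time_s=t, replicate_dfs=dfs, median_df=med,
                    n_infinite_excluded=n_inf)


def fold_change(df_a: DFResult, df_b: DFResult) -> float:
    """Ratio of two discrimination factors (e.g. TE design over plain TMSD)."""
    if df_a.infinite or df_b.infinite:
        raise ValueError("fold change undefined for infinite DFs")
    if not (math.isfinite(df_a.df) and math.isfinite(df_b.df)):
        raise ValueError("fold change requires finite DFs")
    if df_b.df == 0:
        raise ValueError("reference DF is zero")
    return df_a.df / df_b.df
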