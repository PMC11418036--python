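"""Validation metrics for eGFR against measured GFR.

Performance is summarised the way GFR-equation validation studies
report it: median bias (eGFR − mGFR) with a 95% CI, imprecision as the
interquartile range of the bias, and P30/P20 accuracy (the percentage
of estimates within ±30% / ±20% of the measurement) with 95% CIs. Two
equations are declared "different" on a metric only when their 95% CIs
do not overlap — deliberately conservative, and no p-values anywhere.

Method choices (the source studies leave them unstated):

* the median-bias CI is a nonparametric bootstrap percentile interval
  (default 2000 resamples, mandatory seed);
* the proportion CI is the Wald normal approximation by default, which
  matches the printed interval widths of published validation tables;
  a Wilson interval is available behind ``method="wilson"``;
* quantiles use linear interpolation (type-7), the numpy default;
* the ±30%/±20% boundary is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PerformanceSummary",
    "ComparisonVerdict",
    "median_bias",
    "bias_ci",
    "p_accuracy",
    "p_accuracy_ci",
    "iqr_bias",
    "compare_by_ci_overlap",
    "summarize_performance",
    "performance_table",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """All Table-style metrics for one equation on one stratum."""

    equation: str
    stratum: str
    n: int
    median_bias: float = math.nan
    bias_ci: Tuple[float, float] = (math.nan, math.nan)
    bias_iqr_width: float = math.nan
    bias_q1_q3: Tuple[float, float] = (math.nan, math.nan)
    p30: float = math.nan
    p30_ci: Tuple[float, float] = (math.nan, math.nan)
    p20: float = math.nan
    p20_ci: Tuple[float, float] = (math.nan, math.nan)


@dataclass(frozen=True)
class ComparisonVerdict:
    metric: str
    equation_a: str
    equation_b: str
    different: bool
    interval_a: Tuple[float, float]
    interval_b: Tuple[float, float]


def _paired(egfr, mgfr) -> Tuple[np.ndarray, np.ndarray]:
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    if egfr.shape != mgfr.shape or egfr.ndim != 1:
        raise ValueError("egfr and mgfr must be paired 1-D vectors of equal length")
    if egfr.size == 0:
        raise ValueError("empty input")
    return egfr, mgfr


def median_bias(egfr, mgfr) -> float:
    """Median of the pairwise differences eGFR − mGFR."""
    egfr, mgfr = _paired(egfr, mgfr)
    return float(np.median(egfr - mgfr))


def bias_ci(
    egfr,
    mgfr,
    level: float = 0.95,
    n_boot: int = 2000,
    *,
    seed: int,
) -> Tuple[float, float]:
    """Bootstrap percentile CI of the median bias; seed is mandatory."""
    egfr, mgfr = _paired(egfr, mgfr)
    diffs = egfr - mgfr
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 paired observations for a CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    medians = np.median(diffs[idx], axis=1)
    lo, hi = np.quantile(medians, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def p_accuracy(egfr, mgfr, tol: float = 0.30) -> float:
    """Percentage of eGFR within ±tol of mGFR; the boundary counts as within."""
    egfr, mgfr = _paired(egfr, mgfr)
    if np.any(mgfr <= 0):
        raise ValueError("mGFR must be strictly positive")
    within = np.abs(egfr - mgfr) <= tol * mgfr
    return float(100.0 * np.count_nonzero(within) / within.size)


def p_accuracy_ci(
    p: float, n: int, level: float = 0.95, method: str = "wald"
) -> Tuple[float, float]:
    """CI for a percentage, clipped to [0, 100]. Wald by default, Wilson optional."""
    if not (0 <= p <= 100):
        raise ValueError(f"percentage out of range: {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "wald":
        z = stats.norm.ppf((1 + level) / 2)
        half = z * math.sqrt(p * (100 - p) / n)
        return (max(p - half, 0.0), min(p + half, 100.0))
    if method == "wilson":
        count = round(p / 100 * n)
        lo, hi = proportion_confint(count, n, alpha=1 - level, method="wilson")
        return (100 * lo, 100 * hi)
    raise ValueError(f"unknown CI method {method!r}")


def iqr_bias(egfr, mgfr) -> Tuple[float, float, float]:
    """(width, q1, q3) of the bias distribution, type-7 quantiles."""
    egfr, mgfr = _paired(egfr, mgfr)
    if egfr.size < 4:
        raise ValueError("need at least 4 paired observations for an IQR")
    q1, q3 = np.quantile(egfr - mgfr, [0.25, 0.75])
    return float(q3 - q1), float(q1), float(q3)


_METRIC_FIELDS = {"bias": ("median_bias", "bias_ci"), "p30": ("p30", "p30_ci"), "p20": ("p20", "p20_ci")}


def compare_by_ci_overlap(
    a: PerformanceSummary, b: PerformanceSummary, metric: str
) -> ComparisonVerdict:
    """Non-overlapping-CI rule: different iff the intervals share no point.

    Touching endpoints count as overlap (not different).
    """
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRIC_FIELDS)}")
    if a.stratum != b.stratum:
        raise ValueError(
            f"summaries are for different strata ({a.stratum!r} vs {b.stratum!r}); comparison is within-stratum only"
        )
    _, ci_field = _METRIC_FIELDS[metric]
    ia: Tuple[float, float] = getattr(a, ci_field)
    ib: Tuple[float, float] = getattr(b, ci_field)
    different = bool(ia[1] < ib[0] or ib[1] < ia[0])
    return ComparisonVerdict(metric, a.equation, b.equation, different, ia, ib)


def summarize_performance(
    egfr,
    mgfr,
    equation: str,
    stratum: str = "all",
    n_boot: int = 2000,
    *,
    seed: int,
    ci_method: str = "wald",
) -> PerformanceSummary:
    """Full metric set for one equation on one stratum.

    Degenerate strata degrade gracefully: n = 0 yields a row of absent
    metrics, n < 2 has no bias CI, n < 4 no IQR.
    """
    egfr = np.asarray(egfr, dtype=float)
    mgfr = np.asarray(mgfr, dtype=float)
    n = int(egfr.size)
    if n == 0:
        return PerformanceSummary(equation, stratum, 0)
    bias = median_bias(egfr, mgfr)
    ci = bias_ci(egfr, mgfr, seed=seed, n_boot=n_boot) if n >= 2 else (math.nan, math.nan)
    if n >= 4:
        width, q1, q3 = iqr_bias(egfr, mgfr)
    else:
        width, q1, q3 = math.nan, math.nan, math.nan
    p30 = p_accuracy(egfr, mgfr, 0.30)
    p20 = p_accuracy(egfr, mgfr, 0.20)
    return PerformanceSummary(
        equation=equation,
        stratum=stratum,
        n=n,
        median_bias=bias,
        bias_ci=ci,
        bias_iqr_width=width,
        bias_q1_q3=(q1, q3),
        p30=p30,
        p30_ci=p_accuracy_ci(p30, n, method=ci_method),
        p20=p20,
        p20_ci=p_accuracy_ci(p20, n, method=ci_method),
    )


def _better(metric: str, a: PerformanceSummary, b: PerformanceSummary) -> bool:
    if metric == "bias":
        return abs(a.median_bias) < abs(b.median_bias)
    return getattr(a, metric) > getattr(b, metric)


def performance_table(
    cohort: pd.DataFrame,
    equations: Sequence[str],
    strata: Optional[Mapping[str, np.ndarray]] = None,
    *,
    seed: int,
    n_boot: int = 2000,
    mgfr_col: str = "mgfr_ml_min_173",
    ci_method: str = "wald",
) -> pd.DataFrame:
    """One row per equation × stratum, with significance flags.

    ``cohort`` must carry the measured GFR column and one
    ``egfr_<equation>`` column per requested equation. ``strata`` maps
    stratum labels to boolean row masks; None means the whole cohort.
    The flag columns list, per metric, the equations this row beats
    under the non-overlapping-CI rule.
    """
    if mgfr_col not in cohort.columns:
        raise ValueError(f"cohort lacks measured-GFR column {mgfr_col!r}")
    if strata is None:
        strata = {"all": np.ones(len(cohort), dtype=bool)}
    rows: List[dict] = []
    for stratum_label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        sub = cohort.loc[mask]
        summaries: Dict[str, PerformanceSummary] = {}
        for eq in equations:
            col = f"egfr_{eq}"
            if col not in cohort.columns:
                raise ValueError(f"cohort lacks eGFR column {col!r}")
            valid = sub[col].notna() & sub[mgfr_col].notna()
            summaries[eq] = summarize_performance(
                sub.loc[valid, col].to_numpy(),
                sub.loc[valid, mgfr_col].to_numpy(),
                eq,
                stratum_label,
                seed=seed,
                n_boot=n_boot,
                ci_method=ci_method,
            )
        for eq, s in summaries.items():
            flags = {}
            for metric in ("bias", "p30"):
                beaten = []
                for other, so in summaries.items():
                    if other == eq or s.n == 0 or so.n == 0:
                        continue
                    verdict = compare_by_ci_overlap(s, so, metric)
                    if verdict.different and _better(metric, s, so):
                        beaten.append(other)
                flags[f"{metric}_better_than"] = ";".join(beaten)
            rows.append(
                {
                    "stratum": s.stratum,
                    "equation": s.equation,
                    "n": s.n,
                    "median_bias": s.median_bias,
                    "bias_ci_low": s.bias_ci[0],
                    "bias_ci_high": s.bias_ci[1],
                    "iqr_width": s.bias_iqr_width,
                    "iqr_q1": s.bias_q1_q3[0],
                    "iqr_q3": s.bias_q1_q3[1],
                    "p30": s.p30,
                    "p30_ci_low": s.p30_ci[0],
                    "p30_ci_high": s.p30_ci[1],
                    "p20": s.p20,
                    "p20_ci_low": s.p20_ci[0],
                    "p20_ci_high": s.p20_ci[1],
                    **flags,
                }
            )
    return pd.DataFrame(rows)
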