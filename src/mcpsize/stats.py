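"""Cross-technique statistical comparison of apparent-diameter datasets.

Descriptive box-whisker summaries (Tukey hinges, 1.5·IQR outlier fences),
percent differences between technique means, one-way fixed-effects ANOVA,
two-tailed two-sample t-tests (Welch by default — the ultra-thin-section
SD of 32 nm against 17–21 nm elsewhere makes equal variances untenable —
with the pooled variant selectable), and the ratio range of one technique's
SD against all others.

Percent changes are kept at full precision here; rounding to integers is a
reporting-layer concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .synthetic import DiameterDataset

__all__ = [
    "StatsError",
    "InsufficientDataError",
    "TechniqueSummary",
    "ComparisonResult",
    "AnovaResult",
    "summarize",
    "percent_change",
    "anova_oneway",
    "ttest_two_tailed",
    "ttest_from_summary",
    "sd_ratio_range",
]


class StatsError(ValueError):
    pass


class InsufficientDataError(StatsError):
    pass


@dataclass(frozen=True)
class TechniqueSummary:
    """Box-and-whisker summary of one technique's diameters (nm).

    Quartiles are Tukey hinges (medians of the median-exclusive halves);
    whiskers reach the most extreme observations inside the 1.5·IQR fences
    and ``outliers`` lists everything beyond them.
    """

    technique: str
    n: int
    mean_nm: float
    sd_nm: float
    median_nm: float
    q1_nm: float
    q3_nm: float
    whisker_low_nm: float
    whisker_high_nm: float
    outliers: tuple


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison; ``percent_change`` uses the second member of
    ``pair`` as the baseline."""

    pair: tuple
    percent_change: float
    t_stat: float
    df: float
    p_value: float
    variant: str
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False


def _tukey_hinges(sorted_x: np.ndarray):
    n = len(sorted_x)
    half = n // 2
    lower = sorted_x[:half]
    upper = sorted_x[-half:] if half else sorted_x
    return float(np.median(lower)), float(np.median(upper))


def summarize(dataset: DiameterDataset) -> TechniqueSummary:
    """Descriptive statistics of one dataset (sample SD, n−1 denominator)."""
    x = np.sort(dataset.diameters_nm)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 measurements to summarise")
    q1, q3 = _tukey_hinges(x)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return TechniqueSummary(
        technique=dataset.technique,
        n=int(x.size),
        mean_nm=float(x.mean()),
        sd_nm=float(x.std(ddof=1)),
        median_nm=float(np.median(x)),
        q1_nm=q1,
        q3_nm=q3,
        whisker_low_nm=float(inside.min()),
        whisker_high_nm=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )


def percent_change(value: float, baseline: float) -> float:
    """``100 · (value − baseline) / baseline``; baseline must be positive."""
    if baseline <= 0:
        raise StatsError("baseline must be > 0")
    return 100.0 * (value - baseline) / baseline


def anova_oneway(datasets) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across technique datasets.

    The fully degenerate case (zero variance within every group *and* equal
    group means) is reported as F = 0, p = 1 with the ``degenerate`` flag.
    """
    groups = [np.asarray(d.diameters_nm, dtype=float) for d in datasets]
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs at least 2 records")
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if within_var == 0 and np.allclose(means, means[0]):
        return AnovaResult(0.0, df_between, df_within, 1.0, degenerate=True)
    f_stat, p_value = sps.f_oneway(*groups)
    return AnovaResult(float(f_stat), df_between, df_within, float(p_value))


def _welch_df(v1, n1, v2, n2):
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def ttest_two_tailed(
    a: DiameterDataset, b: DiameterDataset, variant: str = "welch"
) -> ComparisonResult:
    """Two-sided two-sample t-test of mean apparent diameter.

    ``variant='welch'`` (default) allows unequal group variances;
    ``'pooled'`` assumes them equal.  Equal constant groups are reported as
    t = 0, p = 1 with the ``degenerate`` flag.
    """
    if variant not in ("welch", "pooled"):
        raise StatsError("variant must be 'welch' or 'pooled'")
    xa, xb = a.diameters_nm, b.diameters_nm
    if len(xa) < 2 or len(xb) < 2:
        raise InsufficientDataError("each group needs at least 2 records")
    pct = percent_change(float(xa.mean()), float(xb.mean()))
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0 and math.isclose(xa.mean(), xb.mean()):
        df = _welch_df(1, len(xa), 1, len(xb)) if variant == "welch" else len(xa) + len(xb) - 2
        return ComparisonResult((a.technique, b.technique), pct, 0.0, float(df), 1.0, variant, True)
    res = sps.ttest_ind(xa, xb, equal_var=(variant == "pooled"))
    return ComparisonResult(
        pair=(a.technique, b.technique),
        percent_change=pct,
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
    )


def ttest_from_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    variant: str = "welch",
    labels=("a", "b"),
) -> ComparisonResult:
    """Two-sided t-test from summary statistics alone (n, mean, sample SD).

    Useful when only published group moments are available; identical in
    distribution to the raw-data test under normality.
    """
    if variant not in ("welch", "pooled"):
        raise StatsError("variant must be 'welch' or 'pooled'")
    if n1 < 2 or n2 < 2 or sd1 < 0 or sd2 < 0:
        raise StatsError("need n >= 2 and non-negative SDs")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    df = (
        n1 + n2 - 2
        if variant == "pooled"
        else _welch_df(sd1**2, n1, sd2**2, n2)
    )
    return ComparisonResult(
        pair=tuple(labels),
        percent_change=percent_change(mean1, mean2),
        t_stat=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        variant=variant,
    )


def sd_ratio_range(target: TechniqueSummary, others) -> tuple:
    """(min, max) of ``target.sd_nm / other.sd_nm`` over the other techniques."""
    others = list(others)
    if not others:
        raise StatsError("need at least one other summary")
    if target.sd_nm <= 0 or any(o.sd_nm <= 0 for o in others):
        raise StatsError("all SDs must be > 0")
    ratios = [target.sd_nm / o.sd_nm for o in others]
    return (min(ratios), max(ratios))
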