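"""Cohort-level statistics: group comparisons, eligibility filtering,
median-split survival stratification, and linear association.

Conventions: all tests are two-sided; significance at alpha = 0.05.
Inter-group comparisons use the Mann-Whitney U test (exact null when the
smaller sample has <= 8 observations and the pooled data are tie-free,
tie-corrected normal approximation otherwise, without continuity
correction so that identical samples give p = 1 exactly). Intra-group
paired comparisons use the Wilcoxon signed-rank test (zero differences
dropped; exact null up to n = 15 after zero removal). Survival curves are
product-limit (Kaplan-Meier) estimates compared with the two-group
log-rank (Mantel-Cox) test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .core import NodeMetadata
from .metrics import NodeMetrics

__all__ = [
    "SplitLabel",
    "SurvivalRecord",
    "KMResult",
    "compare_groups",
    "compare_paired",
    "median_split",
    "filter_survival_cohort",
    "km_logrank",
    "linear_assoc",
]


class SplitLabel(enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient disease-free follow-up, measured from the date of surgery."""

    patient_id: str
    time: float  # years of disease-free follow-up
    event: bool  # relapse observed
    covariate: float  # the node metric being stratified

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"follow-up time must be > 0, got {self.time}")


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test. Returns (U statistic, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if min(a.size, b.size) <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_paired(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Pairs are matched by index; zero differences are dropped before
    ranking. All-zero differences are degenerate and give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired samples must have equal length ({a.size} vs {b.size})")
    if a.size == 0:
        raise ValueError("paired samples must be non-empty")
    d = a - b
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        return 1.0
    method = "exact" if n_nonzero <= 15 else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def median_split(values: Sequence[float]) -> list[SplitLabel]:
    """Rank-based LOW/HIGH split with |n_low - n_high| <= 1.

    Values are sorted ascending with stable order; the lower half is LOW,
    the upper half HIGH; for odd n the middle item goes LOW. Splitting at
    the median avoids any biased choice of threshold. All-identical values
    admit no informative split and raise.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("median split needs at least 2 values")
    if np.unique(vals).size == 1:
        raise ValueError("degenerate split: all values identical")
    order = np.argsort(vals, kind="stable")
    n_low = (vals.size + 1) // 2
    labels = [SplitLabel.HIGH] * vals.size
    for i in order[:n_low]:
        labels[i] = SplitLabel.LOW
    return labels


def filter_survival_cohort(
    cohort: Sequence[tuple[NodeMetrics, NodeMetadata]],
) -> list[tuple[NodeMetrics, NodeMetadata]]:
    """Apply the survival-analysis eligibility rules.

    Excluded, in order: (a) patients with less than 5 years of follow-up
    and no relapse (a relapse before 5 years is retained); (b) patients
    with a concurrent cancer at diagnosis; (c) nodes whose percentage of
    DCs falls at or outside the 5th/95th percentile of the (a)+(b)
    survivors — only the center 90% range enters the analysis. Percentiles
    use linear interpolation between order statistics; the exclusion at
    both tails is strict (kept iff above the 5th and below the 95th).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    prefiltered = [
        (nm, md)
        for nm, md in cohort
        if (md.followup_years >= 5.0 or md.relapse_event) and not md.concurrent_cancer
    ]
    if not prefiltered:
        return []
    pct = np.array([nm.pct_dcs for nm, _ in prefiltered], dtype=float)
    lo, hi = np.percentile(pct, [5, 95])
    return [(nm, md) for (nm, md), v in zip(prefiltered, pct) if lo < v < hi]


@dataclass
class KMResult:
    """Two Kaplan-Meier curves and the log-rank comparison between them."""

    curve_low: pd.DataFrame  # columns: time, survival
    curve_high: pd.DataFrame
    chi_square: float
    p_value: float
    median_low: float
    median_high: float


def km_logrank(
    records: Sequence[SurvivalRecord], labels: Sequence[SplitLabel]
) -> KMResult:
    """Kaplan-Meier curves per stratum and the two-group log-rank test.

    Event-free patients are censored at their last follow-up. The p-value
    is two-sided from the chi-square(1) reference.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels length mismatch")
    strata = {lab: [r for r, l in zip(records, labels) if l is lab] for lab in SplitLabel}
    if not strata[SplitLabel.LOW] or not strata[SplitLabel.HIGH]:
        raise ValueError("both LOW and HIGH strata must be non-empty")

    curves: dict[SplitLabel, pd.DataFrame] = {}
    medians: dict[SplitLabel, float] = {}
    for lab, recs in strata.items():
        kmf = KaplanMeierFitter()
        kmf.fit(
            durations=[r.time for r in recs],
            event_observed=[r.event for r in recs],
            label=lab.value,
        )
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[lab] = sf
        medians[lab] = float(kmf.median_survival_time_)

    lo, hi = strata[SplitLabel.LOW], strata[SplitLabel.HIGH]
    res = logrank_test(
        [r.time for r in lo],
        [r.time for r in hi],
        event_observed_A=[r.event for r in lo],
        event_observed_B=[r.event for r in hi],
    )
    return KMResult(
        curve_low=curves[SplitLabel.LOW],
        curve_high=curves[SplitLabel.HIGH],
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        median_low=medians[SplitLabel.LOW],
        median_high=medians[SplitLabel.HIGH],
    )


def linear_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of y on x. Returns (slope, R^2, two-sided p).

    R^2 is the squared Pearson correlation; the slope p-value comes from
    the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.unique(x).size == 1:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
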