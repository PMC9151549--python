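"""Alpha diversity of a sample's LTR pool and condition-comparison tests.

Shannon entropy is reported in nats; evenness is Shannon divided by log
richness (undefined for a single category); Chao1 uses the bias-corrected
estimator S_obs + n1(n1-1)/(2(n2+1)).  Group comparisons follow a gated
procedure: Shapiro-Wilk normality per group and a Levene variance test
decide between a one-tailed Welch t-test and a one-tailed Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DiversityProfile",
    "GroupComparison",
    "shannon",
    "evenness",
    "chao1",
    "diversity_profile",
    "compare_groups",
]


@dataclass
class DiversityProfile:
    shannon: float
    chao1: float
    evenness: Optional[float]  # None when a single category is observed
    otu_count: int
    s_obs: int
    n1: int  # singletons
    n2: int  # doubletons


@dataclass
class GroupComparison:
    metric: str
    levene_p: float
    shapiro_p: tuple[float, float]
    chosen_test: str  # "welch-t" or "mann-whitney"
    statistic: float
    p_value: float
    direction: str


def _positive_counts(counts: Sequence[float]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 0):
        raise ValueError("counts must be nonnegative and nonempty")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("need at least one positive count")
    return c


def shannon(counts: Sequence[float]) -> float:
    """Shannon index H = -sum p_i ln p_i over positive categories, in nats."""
    c = _positive_counts(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def evenness(counts: Sequence[float]) -> float:
    """Pielou evenness H / ln(S_obs); requires at least two categories."""
    c = _positive_counts(counts)
    if c.size < 2:
        raise ValueError("evenness undefined for a single observed category")
    return shannon(c) / float(np.log(c.size))


def chao1(counts: Sequence[float], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton and doubleton counts.

    Bias-corrected (default): S_obs + n1(n1-1)/(2(n2+1)).  The classic form
    S_obs + n1^2/(2 n2) is available but undefined when n2 = 0.
    """
    c = _positive_counts(counts)
    s_obs = c.size
    n1 = int(np.count_nonzero(c == 1))
    n2 = int(np.count_nonzero(c == 2))
    if bias_corrected:
        return float(s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1)))
    if n2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined with no doubletons")
    return float(s_obs + n1 * n1 / (2.0 * n2))


def diversity_profile(
    counts: Sequence[float], otu_labels: Optional[Sequence[int]] = None
) -> DiversityProfile:
    """Full alpha-diversity profile of an abundance vector.

    With ``otu_labels`` (one label per variant), indices are computed on
    OTU-aggregated abundances — the default convention for LTR pools — and
    ``otu_count`` is the number of clusters; otherwise the vector is used
    as-is and ``otu_count`` equals observed richness.
    """
    c = np.asarray(counts, dtype=float)
    if otu_labels is not None:
        labels = np.asarray(otu_labels)
        if labels.size != c.size:
            raise ValueError("one OTU label per variant required")
        c = np.array([c[labels == u].sum() for u in np.unique(labels)])
    c = _positive_counts(c)
    s_obs = int(c.size)
    return DiversityProfile(
        shannon=shannon(c),
        chao1=chao1(c),
        evenness=evenness(c) if s_obs > 1 else None,
        otu_count=s_obs,
        s_obs=s_obs,
        n1=int(np.count_nonzero(c == 1)),
        n2=int(np.count_nonzero(c == 2)),
    )


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    metric: str = "metric",
    alpha_gate: float = 0.05,
    direction: str = "greater",
    levene_center: str = "mean",
) -> GroupComparison:
    """Gated two-group comparison of a diversity metric.

    Shapiro-Wilk on each group and Levene's test (mean-centered by default)
    act as gates: if all three p-values exceed ``alpha_gate`` a one-tailed
    Welch t-test is used, otherwise a one-tailed Mann-Whitney U.
    ``direction`` is the alternative for group A relative to group B
    ("greater" or "less").
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    sw_a = float(stats.shapiro(a).pvalue)
    sw_b = float(stats.shapiro(b).pvalue)
    lev = float(stats.levene(a, b, center=levene_center).pvalue)
    if sw_a > alpha_gate and sw_b > alpha_gate and lev > alpha_gate:
        res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
        chosen = "welch-t"
    else:
        res = stats.mannwhitneyu(a, b, alternative=direction)
        chosen = "mann-whitney"
    return GroupComparison(
        metric=metric,
        levene_p=lev,
        shapiro_p=(sw_a, sw_b),
        chosen_test=chosen,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
    )
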