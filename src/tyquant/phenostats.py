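"""Survival regression, importance weights, and the surrounding statistics.

The central model is an ordinary least-squares fit of heat-shock survival on
two predictors — membrane unsaturated-lipid content (TULA, %) and the
transposon-activity statistic Ta2 — with an intercept.  The report mirrors a
standard commercial-statistics regression output: unstandardized and
standardized coefficients, t and p per predictor, zero-order/partial/part
correlations, tolerance and VIF, model R/R^2/adjusted R^2, the F test, and
the squared partial correlations used as importance weights.

Identities used throughout (k predictors, df = n - k - 1):
    partial_j = t_j / sqrt(t_j^2 + df)
    part_j    = t_j * sqrt((1 - R^2) / df)
    adj_R^2   = 1 - (1 - R^2)(n - 1)/(n - k - 1)
    F         = (R^2/k) / ((1 - R^2)/(n - k - 1))
    VIF_j     = 1 / tolerance_j,  tolerance_j = 1 - R^2 of x_j on the others

Also provided: the 2^-ddCt fold-change rule for qRT-PCR, expression
correlation flags against an anchor gene, and the stress-assay group tests
(Kruskal-Wallis omnibus; pairwise Wilcoxon rank-sum and Dunn z-tests, each
Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PredictorStats",
    "RegressionReport",
    "fit_survival_model",
    "derived_stats",
    "weight_ratio",
    "fold_change_ddct",
    "expression_correlation",
    "StressReport",
    "stress_tests",
]


@dataclass
class PredictorStats:
    name: str
    B: float
    SE: float
    beta: float
    t: float
    p: float
    zero_order: float
    partial: float
    part: float
    tolerance: float
    VIF: float


@dataclass
class RegressionReport:
    predictors: list[PredictorStats]
    intercept: float
    intercept_SE: float
    intercept_t: float
    intercept_p: float
    R: float
    R2: float
    adj_R2: float
    SE_est: float
    F: float
    sig_F: float
    df_model: int
    df_resid: int
    n: int
    weights: dict[str, float] = field(default_factory=dict)
    weight_ratio: Optional[float] = None

    def predictor(self, name: str) -> PredictorStats:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


def fit_survival_model(
    data: pd.DataFrame,
    response: str = "survival45",
    predictors: Sequence[str] = ("tula", "ta2"),
) -> RegressionReport:
    """OLS fit of survival on two predictors with a full regression report.

    Requires n >= k + 2 observations and a non-singular design.  The weights
    block holds each predictor's squared partial correlation and the ratio
    of the first predictor's weight to the second's.
    """
    y = np.asarray(data[response], dtype=float)
    X = np.column_stack([np.asarray(data[p], dtype=float) for p in predictors])
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations, got {n}")
    design = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(design) < k + 1:
        raise ValueError("singular design: predictors are collinear")
    fit = sm.OLS(y, design).fit()

    r2 = float(fit.rsquared)
    df_resid = int(fit.df_resid)
    sd_y = float(np.std(y, ddof=1))
    preds: list[PredictorStats] = []
    for j, name in enumerate(predictors):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        if others.shape[1] > 0:
            aux = sm.OLS(xj, sm.add_constant(others)).fit()
            tol = 1.0 - float(aux.rsquared)
        else:
            tol = 1.0
        t_j = float(fit.tvalues[j + 1])
        preds.append(
            PredictorStats(
                name=name,
                B=float(fit.params[j + 1]),
                SE=float(fit.bse[j + 1]),
                beta=float(fit.params[j + 1]) * float(np.std(xj, ddof=1)) / sd_y,
                t=t_j,
                p=float(fit.pvalues[j + 1]),
                zero_order=float(np.corrcoef(y, xj)[0, 1]),
                partial=t_j / math.sqrt(t_j * t_j + df_resid),
                part=t_j * math.sqrt((1.0 - r2) / df_resid),
                tolerance=tol,
                VIF=1.0 / tol,
            )
        )
    weights = {p.name: p.partial**2 for p in preds}
    w_ratio = None
    if len(preds) == 2 and weights[preds[1].name] > 0:
        w_ratio = weights[preds[0].name] / weights[preds[1].name]
    return RegressionReport(
        predictors=preds,
        intercept=float(fit.params[0]),
        intercept_SE=float(fit.bse[0]),
        intercept_t=float(fit.tvalues[0]),
        intercept_p=float(fit.pvalues[0]),
        R=math.sqrt(r2),
        R2=r2,
        adj_R2=float(fit.rsquared_adj),
        SE_est=math.sqrt(float(fit.mse_resid)),
        F=float(fit.fvalue),
        sig_F=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=df_resid,
        n=n,
        weights=weights,
        weight_ratio=w_ratio,
    )


def derived_stats(
    R2: float, k: int, n: int, t_values: Sequence[float]
) -> dict[str, object]:
    """Closed-form report quantities from printed model-level numbers.

    Given a model's R^2, predictor count k, sample size n and the
    coefficient t statistics, returns the F statistic, adjusted R^2, and the
    partial and part (semipartial) correlation of each predictor.
    """
    if n <= k + 1:
        raise ValueError("need n > k + 1 for positive residual df")
    df = n - k - 1
    t = np.asarray(t_values, dtype=float)
    return {
        "F": (R2 / k) / ((1.0 - R2) / df),
        "adj_R2": 1.0 - (1.0 - R2) * (n - 1) / df,
        "partials": (t / np.sqrt(t * t + df)).tolist(),
        "parts": (t * math.sqrt((1.0 - R2) / df)).tolist(),
    }


def weight_ratio(partials: tuple[float, float]) -> tuple[float, float, Optional[float]]:
    """Squared-partial importance weights (w1, w2) and their ratio w1/w2."""
    p1, p2 = partials
    w1, w2 = p1 * p1, p2 * p2
    return w1, w2, (w1 / w2 if w2 > 0 else None)


def fold_change_ddct(
    ct_target_sample: float,
    ct_ref_gene_sample: float,
    ct_target_control: float,
    ct_ref_gene_control: float,
) -> float:
    """Relative expression by the double-delta quantification-cycle rule.

    fold = 2^-((Ct_t,s - Ct_r,s) - (Ct_t,c - Ct_r,c)).
    """
    for ct in (ct_target_sample, ct_ref_gene_sample, ct_target_control, ct_ref_gene_control):
        if ct <= 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target_sample - ct_ref_gene_sample) - (ct_target_control - ct_ref_gene_control)
    return float(2.0 ** (-ddct))


def expression_correlation(
    expr: pd.DataFrame, anchor_gene: str, r2_threshold: float = 0.7
) -> pd.DataFrame:
    """Squared Pearson correlation of every gene with an anchor gene.

    ``expr`` is genes x samples.  Returns a frame indexed by gene with
    columns r2, sign (+1/-1/0), flag (r2 > threshold) and defined (False for
    zero-variance expression vectors, whose correlation is undefined).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if anchor_gene not in expr.index:
        raise KeyError(anchor_gene)
    anchor = expr.loc[anchor_gene].to_numpy(dtype=float)
    if np.std(anchor) == 0:
        raise ValueError("anchor gene has zero variance")
    rows = []
    for gene in expr.index:
        v = expr.loc[gene].to_numpy(dtype=float)
        if np.std(v) == 0:
            rows.append((gene, np.nan, 0, False, False))
            continue
        r = float(np.corrcoef(anchor, v)[0, 1])
        rows.append((gene, r * r, int(np.sign(r)), r * r > r2_threshold, True))
    return pd.DataFrame(
        rows, columns=["gene", "r2", "sign", "flag", "defined"]
    ).set_index("gene")


@dataclass
class StressReport:
    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, wilcoxon_p, wilcoxon_p_bh, dunn_z, dunn_p, dunn_p_bh


def _dunn_z(values: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    pooled = np.concatenate(list(values.values()))
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes, pos = {}, {}, 0
    for g, v in values.items():
        mean_ranks[g] = float(ranks[pos : pos + v.size].mean())
        sizes[g] = v.size
        pos += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    out = {}
    for a, b in itertools.combinations(values, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        out[(a, b)] = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
    return out


def stress_tests(
    colony_counts: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> StressReport:
    """Stress-viability group tests across genotypes.

    Kruskal-Wallis omnibus over all groups, then two pairwise families —
    Wilcoxon rank-sum and Dunn z-tests on the pooled-rank means — each
    Benjamini-Hochberg adjusted.  Identical values in every group yield an
    omnibus p of 1.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in colony_counts.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(v.size < 3 for v in groups.values()):
        raise ValueError("need at least 3 replicates per group")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw = stats.kruskal(*groups.values())
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)

    dunn = _dunn_z(groups)
    rows = []
    for a, b in itertools.combinations(groups, 2):
        va, vb = groups[a], groups[b]
        if np.all(np.concatenate([va, vb]) == va[0]):
            w_p = 1.0
        else:
            w_p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        z = dunn[(a, b)]
        rows.append((a, b, w_p, z, 2.0 * float(stats.norm.sf(abs(z)))))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "wilcoxon_p", "dunn_z", "dunn_p"])
    pw["wilcoxon_p_bh"] = multipletests(pw["wilcoxon_p"], method="fdr_bh")[1]
    pw["dunn_p_bh"] = multipletests(pw["dunn_p"], method="fdr_bh")[1]
    pw = pw[["group_a", "group_b", "wilcoxon_p", "wilcoxon_p_bh", "dunn_z", "dunn_p", "dunn_p_bh"]]
    return StressReport(kruskal_stat=kw_stat, kruskal_p=kw_p, pairwise=pw)
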