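"""Group-comparison harness and condition-adjusted regression.

Two-group comparisons follow a fixed decision rule: each group is
checked for normality with the D'Agostino-Pearson test of skewness and
kurtosis; if both pass at ``alpha_norm`` the groups are compared with an
unpaired t test, using Welch's correction when an F-ratio test finds the
variances unequal; otherwise a two-sided Mann-Whitney U test is used.
Groups of three or more are compared by one-way ANOVA with Tukey's
multiple comparisons when all pass normality, else by Kruskal-Wallis
with Dunn's post hoc (Bonferroni-adjusted pairwise z tests on mean
ranks). Orienting is additionally modeled by ordinary least squares with
standard length and treatment condition as covariates, so condition
effects can be separated from body-size effects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "GroupComparison",
    "compare_groups",
    "compare_multi",
    "orienting_regression",
    "dunn_posthoc",
]


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    group_summaries: list[dict]
    pairwise: pd.DataFrame | None = None
    normality_p: tuple = ()
    variance_ratio_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p outside [0, 1]")


def _summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": int(len(x)), "median": float(med), "q1": float(q1),
            "q3": float(q3), "mean": float(np.mean(x))}


def _normality_p(x: np.ndarray) -> float | None:
    """D'Agostino-Pearson p, or None when the sample is too small (< 8)."""
    if len(x) < 8:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(scipy.stats.normaltest(x).pvalue)


def _f_ratio_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-ratio test of equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    return float(min(1.0, 2.0 * scipy.stats.f.sf(f, dfn, dfd)))


def compare_groups(a, b, alpha_norm: float = 0.05) -> GroupComparison:
    """Two-group comparison with the normality-driven test selection rule."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pa, pb = _normality_p(a), _normality_p(b)
    if pa is None or pb is None:
        warnings.warn("group too small for the normality test; "
                      "falling back to Mann-Whitney U")
        both_normal = False
    else:
        both_normal = pa > alpha_norm and pb > alpha_norm
    pf = None
    if both_normal:
        pf = _f_ratio_p(a, b)
        if pf > 0.05:
            res = scipy.stats.ttest_ind(a, b, equal_var=True)
            name = "Student t"
        else:
            res = scipy.stats.ttest_ind(a, b, equal_var=False)
            name = "Welch t"
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # identical constant groups
            stat, p = 0.0, 1.0
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(test=name, statistic=stat, p=p,
                           group_summaries=[_summary(a), _summary(b)],
                           normality_p=(pa, pb), variance_ratio_p=pf)


def dunn_posthoc(groups: list[np.ndarray], labels: list | None = None
                 ) -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks, Bonferroni adjusted."""
    k = len(groups)
    labels = labels if labels is not None else list(range(k))
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    rows = []
    n_pairs = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": float(z),
                     "p": float(p), "p_adj": float(min(1.0, p * n_pairs))})
    return pd.DataFrame(rows)


def compare_multi(groups: list, alpha_norm: float = 0.05,
                  labels: list | None = None) -> GroupComparison:
    """ANOVA + Tukey when all groups are normal, else Kruskal-Wallis + Dunn."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least three groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    labels = labels if labels is not None else list(range(len(groups)))
    norm_ps = [_normality_p(g) for g in groups]
    all_normal = all(p is not None and p > alpha_norm for p in norm_ps)
    if all_normal:
        res = scipy.stats.f_oneway(*groups)
        tk = scipy.stats.tukey_hsd(*groups)
        rows = [{"group_a": labels[i], "group_b": labels[j],
                 "p_adj": float(tk.pvalue[i, j])}
                for i, j in itertools.combinations(range(len(groups)), 2)]
        pairwise = pd.DataFrame(rows)
        name = "one-way ANOVA + Tukey"
    else:
        res = scipy.stats.kruskal(*groups)
        pairwise = dunn_posthoc(groups, labels)
        name = "Kruskal-Wallis + Dunn"
    return GroupComparison(test=name, statistic=float(res.statistic),
                           p=float(res.pvalue),
                           group_summaries=[_summary(g) for g in groups],
                           pairwise=pairwise,
                           normality_p=tuple(norm_ps))


def orienting_regression(orienting, length, condition) -> pd.DataFrame:
    """OLS: orienting ~ intercept + standard length + condition indicator.

    ``condition`` may be a 0/1 indicator or a two-level label array.
    Returns the coefficient table (coef, se, t, p, CI bounds).
    """
    y = np.asarray(orienting, float)
    x_len = np.asarray(length, float)
    cond = np.asarray(condition)
    if cond.dtype.kind not in "ifb":
        levels = pd.unique(cond)
        if len(levels) != 2:
            raise ValueError("condition must have exactly two levels")
        cond = (cond == levels[1]).astype(float)
    cond = cond.astype(float)
    if len(np.unique(x_len)) < 3:
        raise ValueError("need at least three distinct lengths")
    if len(np.unique(cond)) < 2:
        raise ValueError("both conditions must be present")
    X = np.column_stack([x_len, cond])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(x_len), X])) < 3:
        raise ValueError("length and condition are perfectly collinear")
    model = sm.OLS(y, sm.add_constant(pd.DataFrame(
        {"length": x_len, "condition": cond}))).fit()
    ci = model.conf_int()
    return pd.DataFrame({
        "coef": model.params,
        "se": model.bse,
        "t": model.tvalues,
        "p": model.pvalues,
        "ci_low": ci[0],
        "ci_high": ci[1],
    })
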