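"""Inferential statistics used by the analysis.

Thin, contract-checked wrappers around the standard routines (scipy for
rank tests, ANOVA and OLS) plus two model-comparison F-tests built from
explicit design matrices: the type-by-era interaction of an unbalanced
two-way layout and the ANCOVA homogeneity-of-slopes test.  The Nemenyi
post hoc for Kruskal-Wallis is implemented here directly, in both the
studentized-range (equal group sizes) and chi-square (unequal sizes)
variants.

Conventions, fixed across the module: two-sided p-values, midranks for
ties, Mann-Whitney U reported as min(U_a, U_b).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss

from .types import RegressionFit, TestResult

__all__ = [
    "mann_whitney_u",
    "kruskal_wallis",
    "nemenyi_posthoc",
    "oneway_anova",
    "twoway_interaction",
    "linear_regression",
    "ancova_slope_homogeneity",
]


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is reported as min(U_a, U_b).  The p-value uses exact
    enumeration when both samples are small (min n <= 20) and the data
    are tie-free, and the tie-corrected normal approximation otherwise.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(n_a, n_b) <= 20 and not has_ties) else "asymptotic"
    res = ss.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, n_a * n_b - u_a)
    return TestResult(
        name="mann_whitney_u",
        statistic=u,
        p_value=float(min(res.pvalue, 1.0)),
        df=None,
        n=(n_a, n_b),
    )


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups, with tie correction."""
    groups = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # Tie correction denominator vanishes; every rank is tied.
        warnings.warn(
            "all values identical across groups; H defined as 0, p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return TestResult(
            name="kruskal_wallis", statistic=0.0, p_value=1.0,
            df=(k - 1,), n=tuple(g.size for g in groups),
        )
    h, p = ss.kruskal(*groups)
    return TestResult(
        name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        df=(k - 1,),
        n=tuple(g.size for g in groups),
    )


def nemenyi_posthoc(
    groups: Sequence, labels: Sequence[str] | None = None, method: str = "auto"
) -> pd.DataFrame:
    """All-pairs Nemenyi post hoc test on mean ranks.

    ``method`` is ``"tukey"`` (studentized-range reference
    distribution, the classical equal-n Nemenyi), ``"chisquare"`` (the
    tie-corrected chi-square variant appropriate for unequal group
    sizes), or ``"auto"`` which picks tukey for equal sizes and
    chisquare otherwise.  Returns a symmetric DataFrame of p-values
    with unit diagonal.
    """
    groups = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(groups)
    if k < 3:
        raise ValueError("nemenyi_posthoc needs at least 3 groups")
    sizes = np.array([g.size for g in groups])
    if method == "auto":
        method = "tukey" if np.all(sizes == sizes[0]) else "chisquare"
    if method not in ("tukey", "chisquare"):
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = ss.rankdata(pooled)  # midranks
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    mean_ranks = np.asarray(mean_ranks)

    # Tie correction factor, 1 when tie-free.
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)

    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            b = 1.0 / sizes[i] + 1.0 / sizes[j]
            if method == "tukey":
                q = diff / np.sqrt(n_total * (n_total + 1) / 24.0 * b)
                pij = float(ss.studentized_range.sf(q, k, np.inf))
            else:
                chi = diff**2 / (n_total * (n_total + 1) / 12.0 * b)
                if tie_c > 0:
                    chi /= tie_c
                pij = float(ss.chi2.sf(chi, k - 1))
            p[i, j] = p[j, i] = min(pij, 1.0)

    if labels is None:
        labels = [f"group_{i}" for i in range(k)]
    return pd.DataFrame(p, index=list(labels), columns=list(labels))


def oneway_anova(*groups) -> TestResult:
    """Classical one-way ANOVA F-test across >= 2 groups."""
    groups = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("oneway_anova needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    sizes = [g.size for g in groups]
    n_total = sum(sizes)
    k = len(groups)
    within_ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    grand = np.concatenate(groups).mean()
    between_ss = sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups))
    if within_ss == 0.0:
        if between_ss == 0.0:
            raise ValueError(
                "zero within-group variance and equal means: F is undefined"
            )
        return TestResult(
            name="oneway_anova", statistic=float("inf"), p_value=0.0,
            df=(k - 1, n_total - k), n=tuple(sizes),
        )
    f, p = ss.f_oneway(*groups)
    return TestResult(
        name="oneway_anova",
        statistic=float(f),
        p_value=float(p),
        df=(k - 1, n_total - k),
        n=tuple(sizes),
    )


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def _model_comparison_f(
    x_full: np.ndarray, x_reduced: np.ndarray, y: np.ndarray, name: str, n_groups=None
) -> TestResult:
    """F-test of a full against a nested reduced linear model via
    residual sums of squares."""
    n = y.size
    df_num = x_full.shape[1] - x_reduced.shape[1]
    df_den = n - x_full.shape[1]
    if df_den <= 0:
        raise ValueError(f"{name}: not enough observations for the full model")
    rss_full = _rss(x_full, y)
    rss_red = _rss(x_reduced, y)
    if rss_full <= 0.0:
        # Saturated (noise-free) data: the reduced model either also
        # fits exactly (F -> 0) or is detectably worse (F -> inf).
        if rss_red <= 1e-10 * max(1.0, float(y @ y)):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(ss.f.sf(f_stat, df_num, df_den))
    return TestResult(
        name=name, statistic=float(f_stat), p_value=p, df=(df_num, df_den), n=n_groups
    )


def twoway_interaction(values, factor_type, factor_era) -> TestResult:
    """Interaction F-test of a two-way (temperature-type x era) layout.

    Unbalanced cells are handled by model comparison: the full
    two-factor model with interaction against the additive model, so
    the reported F isolates the interaction term.
    """
    y = _as_sample(values, "values")
    t_labels = np.asarray(factor_type)
    e_labels = np.asarray(factor_era)
    if not (y.size == t_labels.size == e_labels.size):
        raise ValueError("values and factor labels must have equal length")
    t_levels = list(dict.fromkeys(t_labels.tolist()))
    e_levels = list(dict.fromkeys(e_labels.tolist()))
    for tl in t_levels:
        for el in e_levels:
            if not np.any((t_labels == tl) & (e_labels == el)):
                raise ValueError(f"empty cell: type={tl!r}, era={el!r}")

    t_dummies = np.column_stack([(t_labels == lv).astype(float) for lv in t_levels[1:]])
    e_dummies = np.column_stack([(e_labels == lv).astype(float) for lv in e_levels[1:]])
    inter = np.column_stack(
        [t_dummies[:, i] * e_dummies[:, j]
         for i in range(t_dummies.shape[1]) for j in range(e_dummies.shape[1])]
    )
    ones = np.ones((y.size, 1))
    x_reduced = np.hstack([ones, t_dummies, e_dummies])
    x_full = np.hstack([x_reduced, inter])
    res = _model_comparison_f(x_full, x_reduced, y, "twoway_interaction")
    return res


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least-squares fit of y on x."""
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("linear_regression needs n >= 3")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope is undefined")
    fit = ss.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    residual_sd = float(np.sqrt((resid @ resid) / (x.size - 2)))
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(np.clip(fit.rvalue**2, 0.0, 1.0)),
        n=int(x.size),
        residual_sd=residual_sd,
    )


def ancova_slope_homogeneity(x, y, group) -> TestResult:
    """Homogeneity-of-slopes F-test for a two-group ANCOVA.

    Compares the separate-slopes model (intercept, x, group,
    x * group) against the common-slope model; with two groups the
    interaction has df = (1, n - 4).
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    g_labels = np.asarray(group)
    if not (x.size == y.size == g_labels.size):
        raise ValueError("x, y and group must have equal length")
    levels = list(dict.fromkeys(g_labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"ancova_slope_homogeneity needs exactly 2 groups, got {len(levels)}")
    for lv in levels:
        mask = g_labels == lv
        if mask.sum() < 3:
            raise ValueError(f"group {lv!r} needs at least 3 observations")
        if np.ptp(x[mask]) == 0.0:
            raise ValueError(f"group {lv!r} has constant x")
    g = (g_labels == levels[1]).astype(float)
    ones = np.ones_like(x)
    x_reduced = np.column_stack([ones, x, g])
    x_full = np.column_stack([ones, x, g, x * g])
    return _model_comparison_f(
        x_full, x_reduced, y, "ancova_slope_homogeneity",
        n_groups=tuple(int((g_labels == lv).sum()) for lv in levels),
    )
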