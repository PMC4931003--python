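"""Two-era warming contrast of field temperatures.

Compares body (T_b), air (T_a) and substrate (T_s) temperatures between
two sampling eras a quarter-century apart: per-variable location tests
(the test per variable is a configured routing map, not an automated
normality decision), the temperature-type x era interaction of a
two-way layout, era-wise OLS fits of T_b on each environmental
temperature with homogeneity-of-slopes tests, and "buffering ratios" —
how much of the environmental warming shows up in body temperature.

A buffering ratio delta(T_b)/delta(T_a) well below 1, with unchanged
T_b-on-T_a slopes, is the signature of behavioural compensation:
lizards absorb habitat warming through microhabitat choice and activity
timing rather than through changed thermal physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import stats
from .types import RegressionFit, TemperatureRecord, TestResult

__all__ = [
    "DEFAULT_TEST_ROUTING",
    "VariableContrast",
    "SlopeContrast",
    "EraComparisonReport",
    "compare_eras",
    "sex_pooling_check",
]

#: Which location test to run per variable.  Body and substrate
#: temperatures route to the nonparametric Mann-Whitney test, air
#: temperature to one-way ANOVA.
DEFAULT_TEST_ROUTING: Mapping[str, str] = {
    "t_b": "mann_whitney",
    "t_a": "anova",
    "t_s": "mann_whitney",
}

_VARIABLES = ("t_b", "t_a", "t_s")


@dataclass(frozen=True)
class VariableContrast:
    """One variable's era means +- SE, delta, and location test."""

    variable: str
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    delta: float  # era_b - era_a
    test: TestResult


@dataclass(frozen=True)
class SlopeContrast:
    """Era-wise OLS fits of T_b on a predictor plus the ANCOVA
    homogeneity-of-slopes test."""

    predictor: str
    fit_a: RegressionFit
    fit_b: RegressionFit
    homogeneity: TestResult


@dataclass(frozen=True)
class EraComparisonReport:
    era_a: str
    era_b: str
    variables: Dict[str, VariableContrast]
    interaction: TestResult
    slopes: Dict[str, SlopeContrast]
    buffering: Dict[str, float]  # e.g. "tb_vs_ta" -> delta(T_b)/delta(T_a)


def _values(records: Sequence[TemperatureRecord], var: str) -> np.ndarray:
    vals = [getattr(r, var) for r in records]
    present = np.asarray([v for v in vals if v is not None], dtype=float)
    n_missing = len(vals) - present.size
    if n_missing > 0.5 * len(vals):
        raise ValueError(
            f"{var} missing in {n_missing}/{len(vals)} records of era "
            f"{records[0].era!r}; more than half the era is unusable"
        )
    return present


def _mean_se(x: np.ndarray) -> Tuple[float, float]:
    se = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")
    return float(x.mean()), se


def _location_test(a: np.ndarray, b: np.ndarray, how: str) -> TestResult:
    if how == "mann_whitney":
        return stats.mann_whitney_u(a, b)
    if how == "anova":
        return stats.oneway_anova(a, b)
    raise ValueError(f"unknown location test {how!r}")


def compare_eras(
    records_a: Sequence[TemperatureRecord],
    records_b: Sequence[TemperatureRecord],
    test_routing: Optional[Mapping[str, str]] = None,
) -> EraComparisonReport:
    """Full two-era contrast of T_b, T_a and T_s.

    ``records_a`` is the earlier era, ``records_b`` the later; deltas
    are later minus earlier.  Missing values of a variable are dropped
    per era (an error is raised if more than half an era's records lack
    it).  The interaction test pools all three variables in long format
    and isolates the type x era term by model comparison.
    """
    records_a = list(records_a)
    records_b = list(records_b)
    if not records_a or not records_b:
        raise ValueError("both eras must be non-empty")
    routing = dict(DEFAULT_TEST_ROUTING)
    if test_routing:
        routing.update(test_routing)
    era_a = records_a[0].era
    era_b = records_b[0].era

    variables: Dict[str, VariableContrast] = {}
    long_vals, long_type, long_era = [], [], []
    for var in _VARIABLES:
        a = _values(records_a, var)
        b = _values(records_b, var)
        mean_a, se_a = _mean_se(a)
        mean_b, se_b = _mean_se(b)
        variables[var] = VariableContrast(
            variable=var,
            mean_a=mean_a, se_a=se_a, n_a=int(a.size),
            mean_b=mean_b, se_b=se_b, n_b=int(b.size),
            delta=mean_b - mean_a,
            test=_location_test(a, b, routing[var]),
        )
        long_vals.append(np.concatenate([a, b]))
        long_type.extend([var] * (a.size + b.size))
        long_era.extend([era_a] * a.size + [era_b] * b.size)

    interaction = stats.twoway_interaction(
        np.concatenate(long_vals), np.asarray(long_type), np.asarray(long_era)
    )

    slopes: Dict[str, SlopeContrast] = {}
    for pred in ("t_a", "t_s"):
        pairs_a = [(getattr(r, pred), r.t_b) for r in records_a if getattr(r, pred) is not None]
        pairs_b = [(getattr(r, pred), r.t_b) for r in records_b if getattr(r, pred) is not None]
        xa, ya = map(np.asarray, zip(*pairs_a))
        xb, yb = map(np.asarray, zip(*pairs_b))
        fit_a = stats.linear_regression(xa, ya)
        fit_b = stats.linear_regression(xb, yb)
        hom = stats.ancova_slope_homogeneity(
            np.concatenate([xa, xb]),
            np.concatenate([ya, yb]),
            np.asarray([era_a] * xa.size + [era_b] * xb.size),
        )
        slopes[pred] = SlopeContrast(
            predictor=pred, fit_a=fit_a, fit_b=fit_b, homogeneity=hom
        )

    def _ratio(num: float, den: float) -> float:
        return num / den if den != 0 else float("nan")

    buffering = {
        "tb_vs_ta": _ratio(variables["t_b"].delta, variables["t_a"].delta),
        "tb_vs_ts": _ratio(variables["t_b"].delta, variables["t_s"].delta),
    }
    return EraComparisonReport(
        era_a=era_a,
        era_b=era_b,
        variables=variables,
        interaction=interaction,
        slopes=slopes,
        buffering=buffering,
    )


def sex_pooling_check(
    records: Sequence[TemperatureRecord], alpha: float = 0.05
) -> Tuple[TestResult, bool]:
    """One-way ANOVA of body temperature by sex.

    Returns the test plus a pooling recommendation: ``True`` when the
    sexes do not differ at level ``alpha`` and may be pooled for
    further analyses.
    """
    males = np.asarray([r.t_b for r in records if r.sex == "male"], dtype=float)
    females = np.asarray([r.t_b for r in records if r.sex == "female"], dtype=float)
    if males.size == 0 or females.size == 0:
        raise ValueError("sex_pooling_check needs records of both sexes")
    res = stats.oneway_anova(males, females)
    return res, bool(res.p_value > alpha)
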