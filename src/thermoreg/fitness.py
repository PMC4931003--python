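"""Thermal safety margins and an illustrative performance curve.

The thermal safety margin is the optimal temperature for physiological
performance (here the lacertid sprint-speed optimum, 34.53 +- 0.50 deg
C) minus the mean field body temperature: positive margins mean lizards
run colder than their optimum, the "safe" side under warming because
thermal performance curves are left-skewed — performance rises
gradually from the critical minimum to the optimum and collapses
sharply above it (Jensen's-inequality asymmetry), so overshooting the
optimum costs far more than an equal shortfall below it.

The performance curve provided here is illustrative only (for margin
diagrams); it is a minimal piecewise shape with the correct skew, not a
fit to any sprint-speed data, and its critical-temperature defaults are
synthetic placeholders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["OptimalTemperature", "safety_margin", "skewed_performance_curve"]


@dataclass(frozen=True)
class OptimalTemperature:
    """Optimal temperature for performance/fitness, deg C."""

    t_opt: float
    se: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_opt <= 50.0):
            raise ValueError(f"t_opt={self.t_opt} outside the plausible [0, 50] degC")
        if self.se < 0:
            raise ValueError("se must be non-negative")


#: Sprint-performance optimum for the study species' family
#: (lacertids), used as the fitness-optimum estimate.
LACERTID_SPRINT_OPTIMUM = OptimalTemperature(
    t_opt=34.53, se=0.50, source="lacertid sprint-speed optimum"
)


def safety_margin(mean_tb: float, opt: OptimalTemperature) -> float:
    """Thermal safety margin: t_opt - mean body temperature, deg C.

    Positive = body temperatures below the optimum (room to warm before
    fitness declines); negative = the optimum has been exceeded.
    """
    mean_tb = float(mean_tb)
    if not math.isfinite(mean_tb):
        raise ValueError(f"mean_tb must be finite, got {mean_tb!r}")
    return opt.t_opt - mean_tb


def skewed_performance_curve(
    t,
    t_opt: float = LACERTID_SPRINT_OPTIMUM.t_opt,
    ct_min: float = 5.0,
    ct_max: float = 42.0,
    rise_exponent: float = 2.0,
):
    """Illustrative left-skewed thermal performance curve in [0, 1].

    Piecewise: relative performance rises from 0 at ``ct_min`` to 1 at
    ``t_opt`` as ``((t - ct_min)/(t_opt - ct_min)) ** rise_exponent``
    and falls linearly back to 0 at ``ct_max``.  With the rise span
    much wider than the fall span the decline is steeper than the rise
    at any equal distance from the optimum — the Jensen-type asymmetry
    that makes overshooting costly.  Outside [ct_min, ct_max] the curve
    is 0.

    The default critical temperatures are synthetic placeholders chosen
    for a plausible diagram; they are not species measurements.  This
    function exists for plots and margin visualisation only.
    """
    if not (ct_min < t_opt < ct_max):
        raise ValueError(f"need ct_min < t_opt < ct_max, got {ct_min}, {t_opt}, {ct_max}")
    if rise_exponent <= 0:
        raise ValueError("rise_exponent must be positive")
    t_arr = np.asarray(t, dtype=float)
    rise = np.clip((t_arr - ct_min) / (t_opt - ct_min), 0.0, 1.0) ** rise_exponent
    fall = np.clip((ct_max - t_arr) / (ct_max - t_opt), 0.0, 1.0)
    out = np.where(t_arr <= t_opt, rise, fall)
    out = np.where((t_arr < ct_min) | (t_arr > ct_max), 0.0, out)
    if np.isscalar(t) or (hasattr(t, "ndim") and getattr(t, "ndim", 1) == 0):
        return float(out)
    return out
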