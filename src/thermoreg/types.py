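"""Domain containers for the thermal-biology analysis.

The analysis revolves around four kinds of temperature observations:

* body temperatures (``t_b``) of active lizards captured in the field,
  with air (``t_a``, 1 cm above the capture point) and substrate
  (``t_s``) temperatures taken at capture;
* selected temperatures (``t_sel``) measured in a cost-free laboratory
  thermal gradient, from which the preferred temperature range (PTR,
  the central 50% of selections) is estimated;
* operative temperatures (``t_e``) recorded by physical null models
  (copper cylinders) placed in nine named microhabitats — the
  temperature a non-thermoregulating animal would reach there;
* deviations of body/operative temperatures from the PTR (``d_b``,
  ``d_e``), the ingredients of the Hertz effectiveness index
  ``E = 1 - mean(d_b) / mean(d_e)``.

All containers validate their physical invariants at construction so
that downstream numerics never see out-of-range values.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SEXES = ("male", "female", "unknown")

#: The closed set of thermal microhabitat categories monitored by the
#: copper-model loggers.
MICROHABITATS = (
    "flat_rock",
    "moss",
    "soil",
    "grass",
    "rock_south",
    "rock_east",
    "rock_north",
    "rock_west",
    "under_rock",
)

# Plausibility window for any field/logger temperature, in deg C.
TEMP_MIN, TEMP_MAX = -10.0, 70.0

# Span of the laboratory thermal gradient, in deg C.
GRADIENT_MIN, GRADIENT_MAX = 20.0, 60.0


def _check_temp(name: str, value: Optional[float], *, optional: bool = False) -> Optional[float]:
    if value is None:
        if optional:
            return None
        raise ValueError(f"{name} is mandatory")
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if not (TEMP_MIN <= value <= TEMP_MAX):
        raise ValueError(
            f"{name}={value} degC outside the plausibility window "
            f"[{TEMP_MIN}, {TEMP_MAX}]"
        )
    return value


@dataclass(frozen=True)
class TemperatureRecord:
    """One captured lizard: body, air and substrate temperature.

    ``time`` is minutes since midnight GMT; ``era`` is an opaque
    sampling-era label such as ``"1983-1989"`` or ``"2012"``.  Air and
    substrate temperatures may be missing (``None``) for individual
    captures; body temperature is always present.
    """

    lizard_id: str
    sex: str
    date: datetime.date
    time: float
    era: str
    t_b: float
    t_a: Optional[float] = None
    t_s: Optional[float] = None
    svl: Optional[float] = None   # snout-vent length, mm
    mass: Optional[float] = None  # g

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.era:
            raise ValueError("era label must be non-empty")
        if not (0.0 <= float(self.time) < 1440.0):
            raise ValueError(f"time={self.time} outside [0, 1440) minutes")
        _check_temp("t_b", self.t_b)
        _check_temp("t_a", self.t_a, optional=True)
        _check_temp("t_s", self.t_s, optional=True)

    @property
    def hour(self) -> int:
        """GMT hour of capture, by truncation."""
        return int(self.time // 60)


@dataclass(frozen=True)
class SelectedTemperature:
    """One selected body temperature from the laboratory gradient."""

    lizard_id: str
    sex: str
    hour: int
    t_sel: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"gradient sex must be male/female, got {self.sex!r}")
        if not (9 <= int(self.hour) < 18):
            raise ValueError(f"gradient hour {self.hour} outside [9, 18)")
        t = float(self.t_sel)
        if not math.isfinite(t) or not (GRADIENT_MIN <= t <= GRADIENT_MAX):
            raise ValueError(
                f"t_sel={self.t_sel} outside the gradient span "
                f"[{GRADIENT_MIN}, {GRADIENT_MAX}]"
            )


@dataclass(frozen=True)
class PreferredRange:
    """The preferred temperature range (set-point interval), deg C.

    ``central_fraction`` records which central fraction of gradient
    selections the interval covers (0.5 for the conventional central
    50%).  ``breadth`` (upper - lower) is the "precision of
    thermoregulation": narrower means a more precise thermal specialist.
    """

    lower: float
    upper: float
    central_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("PTR bounds must be finite")
        if self.lower > self.upper:
            raise ValueError(f"PTR lower {self.lower} > upper {self.upper}")
        if not (0.0 < self.central_fraction <= 1.0):
            raise ValueError("central_fraction must be in (0, 1]")

    @property
    def breadth(self) -> float:
        return self.upper - self.lower

    def contains(self, t) -> np.ndarray:
        """Element-wise: is ``t`` inside the closed interval?"""
        t = np.asarray(t, dtype=float)
        return (t >= self.lower) & (t <= self.upper)


@dataclass(frozen=True)
class DeviationSet:
    """Non-negative deviations of temperatures from the PTR.

    ``source`` distinguishes body-temperature deviations (``d_b``,
    accuracy of thermoregulation) from operative-temperature deviations
    (``d_e``, thermal quality of habitat).
    """

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.source not in ("body", "operative"):
            raise ValueError(f"source must be 'body' or 'operative', got {self.source!r}")
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError(f"DeviationSet({self.source}) must hold a non-empty 1-d array")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"DeviationSet({self.source}) contains non-finite values")
        if np.any(vals < 0):
            raise ValueError(f"DeviationSet({self.source}) contains negative deviations")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def se(self) -> float:
        """Standard error of the mean (sample sd / sqrt(n))."""
        if len(self) < 2:
            return float("nan")
        return float(self.values.std(ddof=1) / math.sqrt(len(self)))


@dataclass(frozen=True)
class ThermoregSummary:
    """Bootstrap pseudo-distribution summary of the Hertz indices.

    Means and standard errors (sd of the pseudo-distribution) of mean
    d_b, mean d_e and E over ``n_resamples`` bootstrap resamples.
    ``n_undefined`` counts resamples whose mean d_e* was zero, for which
    E* is undefined and excluded.
    """

    mean_db: float
    se_db: float
    mean_de: float
    se_de: float
    e_index: float
    se_e: float
    n_resamples: int
    seed: int
    n_body: int
    n_operative: int
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if self.mean_db < 0 or self.mean_de < 0:
            raise ValueError("mean deviations must be non-negative")
        if self.e_index > 1.0 + 1e-12:
            raise ValueError(f"E = {self.e_index} exceeds 1")
        for name in ("se_db", "se_de", "se_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class OperativeRecord:
    """One operative-temperature logger reading from a copper model."""

    model_id: str
    microhabitat: str
    date: datetime.date
    time: float
    t_e: float

    def __post_init__(self) -> None:
        if self.microhabitat not in MICROHABITATS:
            raise ValueError(
                f"unknown microhabitat {self.microhabitat!r}; "
                f"expected one of {MICROHABITATS}"
            )
        if not (0.0 <= float(self.time) < 1440.0):
            raise ValueError(f"time={self.time} outside [0, 1440) minutes")
        _check_temp("t_e", self.t_e)

    @property
    def hour(self) -> int:
        return int(self.time // 60)


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with degrees of freedom and p-value."""

    name: str
    statistic: float
    p_value: float
    df: Optional[tuple] = None
    n: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value={self.p_value} outside [0, 1]")
        if self.df is not None:
            df = tuple(self.df) if isinstance(self.df, (tuple, list)) else (self.df,)
            object.__setattr__(self, "df", df)
            if any(d <= 0 for d in df):
                raise ValueError(f"degrees of freedom must be positive, got {df}")


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of one temperature on another."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared={self.r_squared} outside [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)
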