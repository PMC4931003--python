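"""Hertz-protocol mathematics: deviations from the set-point range,
index point estimates, and bootstrap pseudo-distributions.

The protocol scores thermoregulation against a null hypothesis of
thermoconformity.  Every field body temperature and every operative
temperature is reduced to its deviation from the preferred temperature
range (PTR): zero inside the range, distance to the nearer bound
outside.  Three indices follow:

* accuracy of thermoregulation, mean d_b (lower = body temperatures
  closer to the set-points);
* thermal quality of habitat, mean d_e (higher = the habitat, as seen
  by a non-regulating animal, is further from the set-points);
* effectiveness of thermoregulation, E = 1 - mean d_b / mean d_e
  (1 = perfect regulator, 0 = thermoconformer, negative = the animal
  avoids thermally suitable sites).

Uncertainty is attached by a bootstrap: body and operative deviations
are resampled independently (they are unpaired by design), each
resample yields (mean d_b*, mean d_e*, E*), and the pseudo-distribution
mean and standard deviation are reported as point estimate and
standard error.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .types import DeviationSet, PreferredRange, ThermoregSummary

log = logging.getLogger(__name__)

__all__ = [
    "deviation_from_range",
    "compute_deviation_set",
    "effectiveness_index",
    "bootstrap_thermoreg",
]


def deviation_from_range(t: float, ptr: PreferredRange) -> float:
    """Deviation of a single temperature from the set-point range.

    Returns ``max(0, lower - t, t - upper)``: zero anywhere inside the
    closed interval, the distance to the nearer bound outside it.
    """
    t = float(t)
    if not math.isfinite(t):
        raise ValueError(f"temperature must be finite, got {t!r}")
    return max(0.0, ptr.lower - t, t - ptr.upper)


def compute_deviation_set(
    temps: Sequence[float], ptr: PreferredRange, source: str
) -> DeviationSet:
    """Element-wise deviations of ``temps`` from the PTR, order preserved.

    ``source`` is ``"body"`` for d_b or ``"operative"`` for d_e.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError(f"no {source} temperatures to score")
    if not np.all(np.isfinite(temps)):
        raise ValueError(f"{source} temperatures contain non-finite values")
    dev = np.maximum(0.0, np.maximum(ptr.lower - temps, temps - ptr.upper))
    return DeviationSet(values=dev, source=source)


def effectiveness_index(mean_db: float, mean_de: float) -> float:
    """Effectiveness of thermoregulation, ``E = 1 - mean_db / mean_de``.

    E is 1 for a perfect thermoregulator (mean d_b = 0), 0 for a
    thermoconformer (body deviations match habitat deviations), and
    negative when body temperatures sit further from the set-points
    than the habitat would impose.
    """
    if mean_db < 0:
        raise ValueError(f"mean_db must be non-negative, got {mean_db}")
    if mean_de < 0:
        raise ValueError(f"mean_de must be non-negative, got {mean_de}")
    if mean_de == 0:
        raise ValueError(
            "mean d_e is zero: the habitat matches the set-point range "
            "everywhere and E is undefined"
        )
    return 1.0 - mean_db / mean_de


def bootstrap_thermoreg(
    db: DeviationSet,
    de: DeviationSet,
    n_resamples: int = 500,
    *,
    seed: int,
    _chunk: int = 1000,
) -> ThermoregSummary:
    """Bootstrap pseudo-distributions of mean d_b, mean d_e and E.

    For each of ``n_resamples`` resamples, ``len(db)`` deviations are
    drawn with replacement from ``db`` and, independently,
    ``len(de)`` from ``de``; the resample statistics are
    mean d_b*, mean d_e* and E* = 1 - mean d_b*/mean d_e*.  The summary
    reports pseudo-distribution means and standard errors (the sample
    standard deviation of the pseudo-distribution).  Resamples with
    mean d_e* = 0, for which E* is undefined, are excluded from the E
    pseudo-distribution and counted in ``n_undefined``.

    The seed is mandatory: identical ``(db, de, n_resamples, seed)``
    give bit-identical summaries.
    """
    if db.source != "body" or de.source != "operative":
        raise ValueError("bootstrap_thermoreg expects (body, operative) deviation sets")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    n_b, n_e = len(db), len(de)

    means_db = np.empty(n_resamples)
    means_de = np.empty(n_resamples)
    # Chunked so large operative sets (thousands of logger readings
    # times thousands of resamples) never materialise a huge index array.
    for start in range(0, n_resamples, _chunk):
        stop = min(start + _chunk, n_resamples)
        k = stop - start
        idx_b = rng.integers(0, n_b, size=(k, n_b))
        means_db[start:stop] = db.values[idx_b].mean(axis=1)
        idx_e = rng.integers(0, n_e, size=(k, n_e))
        means_de[start:stop] = de.values[idx_e].mean(axis=1)

    defined = means_de > 0.0
    n_undefined = int(n_resamples - defined.sum())
    if n_undefined:
        log.warning(
            "bootstrap_thermoreg: %d of %d resamples had mean d_e* = 0; "
            "their E* is undefined and excluded",
            n_undefined,
            n_resamples,
        )
    if not defined.any():
        raise ValueError("every bootstrap resample had mean d_e* = 0; E is undefined")
    e_star = 1.0 - means_db[defined] / means_de[defined]

    def _sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if x.size > 1 else 0.0

    return ThermoregSummary(
        mean_db=float(means_db.mean()),
        se_db=_sd(means_db),
        mean_de=float(means_de.mean()),
        se_de=_sd(means_de),
        e_index=float(e_star.mean()),
        se_e=_sd(e_star),
        n_resamples=int(n_resamples),
        seed=int(seed),
        n_body=n_b,
        n_operative=n_e,
        n_undefined=n_undefined,
    )
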