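"""Preferred temperature range (PTR) estimation from gradient selections.

The PTR is the central fraction (conventionally 50%) of body
temperatures an animal selects in a cost-free laboratory thermal
gradient, taken as a proxy for its physiological set-point range.
Selections are pooled across individuals and hours; the interval is
the empirical quantile interval [(1-f)/2, (1+f)/2] computed with
linear interpolation between order statistics (the "type 7"
convention that numpy, R and most scientific stacks default to).
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np

from .types import PreferredRange, SelectedTemperature

__all__ = ["compute_ptr", "ptr_breadth"]


def compute_ptr(
    selections: Union[Sequence[SelectedTemperature], Sequence[float]],
    central_fraction: float = 0.5,
) -> PreferredRange:
    """Estimate the PTR as the central ``central_fraction`` of selections.

    Accepts either :class:`SelectedTemperature` records or bare
    temperatures.  With the default fraction 0.5 the bounds are the
    first and third quartiles; ``central_fraction=1`` recovers
    ``[min, max]``.  At least four values are required (quartiles of
    fewer are unstable).
    """
    if not (0.0 < central_fraction <= 1.0):
        raise ValueError("central_fraction must be in (0, 1]")
    vals = np.asarray(
        [s.t_sel if isinstance(s, SelectedTemperature) else float(s) for s in selections],
        dtype=float,
    )
    if vals.size < 4:
        raise ValueError(f"need at least 4 selected temperatures, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("selected temperatures contain non-finite values")
    q_lo = (1.0 - central_fraction) / 2.0
    q_hi = (1.0 + central_fraction) / 2.0
    lower, upper = np.quantile(vals, [q_lo, q_hi], method="linear")
    return PreferredRange(
        lower=float(lower), upper=float(upper), central_fraction=central_fraction
    )


def ptr_breadth(ptr: PreferredRange) -> float:
    """Breadth (upper - lower) of the PTR: the precision of
    thermoregulation, in deg C."""
    return ptr.breadth
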