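"""Operative-temperature profiling per microhabitat and hour.

Copper-model loggers record the operative temperature T_e — the
equilibrium temperature of a non-thermoregulating animal — in nine
microhabitat categories.  This module summarises those series per
(microhabitat, GMT hour) cell, pools them into the habitat
thermal-quality deviation set d_e, flags which hours of the activity
window offer at least one thermally suitable patch (T_e inside the
PTR), and compares microhabitats with a Kruskal-Wallis omnibus test
plus a Nemenyi post hoc and a closest-to-PTR ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import compute_deviation_set
from .stats import kruskal_wallis, nemenyi_posthoc
from .types import (
    MICROHABITATS,
    DeviationSet,
    OperativeRecord,
    PreferredRange,
    TestResult,
)

log = logging.getLogger(__name__)

__all__ = [
    "MicrohabitatProfile",
    "MicrohabitatComparison",
    "SuitabilityResult",
    "summarize_operative",
    "hourly_suitability",
    "compare_microhabitats",
    "thermal_quality",
]

#: Default lizard activity window, GMT hours [start, stop).
ACTIVITY_WINDOW = (9, 18)


@dataclass(frozen=True)
class MicrohabitatProfile:
    """Per-(microhabitat, hour) summary of operative temperatures.

    ``table`` is indexed by (microhabitat, hour) with columns
    ``n, mean, sd, min, max, frac_in_ptr``; global statistics pool all
    in-window readings.
    """

    table: pd.DataFrame
    global_mean: float
    global_sd: float
    n_total: int
    ptr: PreferredRange
    hours: Tuple[int, int]


@dataclass(frozen=True)
class SuitabilityResult:
    """Per-hour availability of a thermally suitable patch."""

    flags: dict  # hour -> bool
    all_hours_covered: bool
    criterion: str


@dataclass(frozen=True)
class MicrohabitatComparison:
    kruskal: TestResult
    nemenyi: pd.DataFrame
    ranking: Tuple[Tuple[str, float], ...]  # (microhabitat, mean deviation), nearest first


def _records_frame(
    records: Iterable[OperativeRecord], hours: Tuple[int, int]
) -> pd.DataFrame:
    rows = []
    n_rejected = 0
    for r in records:
        if r.microhabitat not in MICROHABITATS:
            n_rejected += 1
            continue
        rows.append((r.microhabitat, int(r.time // 60), float(r.t_e)))
    if n_rejected:
        log.warning("rejected %d records with unknown microhabitat labels", n_rejected)
    if not rows:
        raise ValueError("no usable operative records")
    df = pd.DataFrame(rows, columns=["microhabitat", "hour", "t_e"])
    if hours is not None:
        df = df[(df["hour"] >= hours[0]) & (df["hour"] < hours[1])]
        if df.empty:
            raise ValueError(f"no operative records within hours {hours}")
    return df


def summarize_operative(
    records: Iterable[OperativeRecord],
    ptr: PreferredRange,
    hours: Tuple[int, int] = ACTIVITY_WINDOW,
) -> MicrohabitatProfile:
    """Summarise T_e per (microhabitat, hour) cell within the activity
    window, plus the pooled global mean, sd and n.

    Hour assignment truncates the timestamp to its GMT hour.  Records
    with unknown microhabitat labels are rejected and logged.
    """
    df = _records_frame(records, hours)
    df["in_ptr"] = ptr.contains(df["t_e"].to_numpy())
    grp = df.groupby(["microhabitat", "hour"], sort=True)
    table = grp["t_e"].agg(n="size", mean="mean", sd="std", min="min", max="max")
    table["frac_in_ptr"] = grp["in_ptr"].mean()
    return MicrohabitatProfile(
        table=table,
        global_mean=float(df["t_e"].mean()),
        global_sd=float(df["t_e"].std(ddof=1)) if len(df) > 1 else 0.0,
        n_total=int(len(df)),
        ptr=ptr,
        hours=tuple(hours) if hours is not None else None,
    )


def hourly_suitability(
    profile: MicrohabitatProfile,
    ptr: Optional[PreferredRange] = None,
    criterion: str = "any_reading",
) -> SuitabilityResult:
    """Flag, for each hour of the window, whether at least one
    microhabitat offered a suitable patch (T_e inside the PTR).

    ``criterion="any_reading"`` (default) requires >= 1 reading inside
    the PTR in that (microhabitat, hour) cell; ``"hourly_mean"``
    requires the cell mean to fall inside the PTR.
    """
    if ptr is None:
        ptr = profile.ptr
    if criterion not in ("any_reading", "hourly_mean"):
        raise ValueError(f"unknown suitability criterion {criterion!r}")
    tab = profile.table.reset_index()
    if criterion == "any_reading":
        if ptr != profile.ptr:
            # frac_in_ptr was tallied against profile.ptr; per-reading
            # membership in a different interval cannot be recovered
            # from cell summaries.
            raise ValueError(
                "any_reading suitability against a different PTR requires "
                "rebuilding the profile with summarize_operative(records, ptr)"
            )
        ok = tab["frac_in_ptr"] > 0.0
    else:
        ok = (tab["mean"] >= ptr.lower) & (tab["mean"] <= ptr.upper)
    per_hour = ok.groupby(tab["hour"]).any()
    if profile.hours is not None:
        hour_range = range(profile.hours[0], profile.hours[1])
    else:
        hour_range = per_hour.index
    flags = {int(h): bool(per_hour.get(h, False)) for h in hour_range}
    return SuitabilityResult(
        flags=flags,
        all_hours_covered=all(flags.values()),
        criterion=criterion,
    )


def thermal_quality(
    records: Iterable[OperativeRecord],
    ptr: PreferredRange,
    hours: Optional[Tuple[int, int]] = ACTIVITY_WINDOW,
) -> DeviationSet:
    """Habitat thermal quality d_e: deviation of every pooled T_e
    reading from the PTR, unweighted across microhabitats.

    Pass ``hours=None`` to use all 24 h of logger data instead of the
    lizard activity window.
    """
    df = _records_frame(records, hours)
    return compute_deviation_set(df["t_e"].to_numpy(), ptr, source="operative")


def compare_microhabitats(
    records: Iterable[OperativeRecord],
    ptr: PreferredRange,
    hours: Optional[Tuple[int, int]] = ACTIVITY_WINDOW,
) -> MicrohabitatComparison:
    """Kruskal-Wallis omnibus test of T_e across microhabitats, the
    Nemenyi all-pairs matrix, and a closest-to-PTR ranking.

    The ranking orders microhabitats by their mean deviation from the
    PTR, most suitable (smallest mean d_e) first.
    """
    df = _records_frame(records, hours)
    present = [m for m in MICROHABITATS if m in set(df["microhabitat"])]
    if len(present) < 3:
        raise ValueError("compare_microhabitats needs >= 3 microhabitats present")
    groups = [df.loc[df["microhabitat"] == m, "t_e"].to_numpy() for m in present]
    omnibus = kruskal_wallis(groups)
    nemenyi = nemenyi_posthoc(groups, labels=present)
    mean_dev = {
        m: float(
            compute_deviation_set(g, ptr, source="operative").values.mean()
        )
        for m, g in zip(present, groups)
    }
    ranking = tuple(sorted(mean_dev.items(), key=lambda kv: (kv[1], kv[0])))
    return MicrohabitatComparison(kruskal=omnibus, nemenyi=nemenyi, ranking=ranking)
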