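"""CSV schemas, run configuration, pipeline orchestration and reporting.

Three plain-CSV interchange schemas cover the analysis inputs:

* capture records:  ``lizard_id,sex,svl_mm,mass_g,date,time_gmt,era,t_b,t_a,t_s``
* gradient selections: ``lizard_id,sex,hour_gmt,t_sel``
* logger series (long): ``model_id,microhabitat,date,time_gmt,t_e``
  (a wide dialect with one ``<model_id>:<microhabitat>`` column per
  model is also accepted)

Times are GMT minutes since midnight, dates ISO-8601, temperatures
decimal deg C.  Malformed rows are rejected and logged with their line
number; a missing mandatory column is an immediate error.

``run_pipeline`` chains the whole analysis — PTR, Hertz indices with
bootstrap, microhabitat profile and suitability, era comparison,
safety margins — and writes a machine-readable JSON bundle plus
human-readable tables.  Identical config and seed give byte-identical
JSON output.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import era as era_mod
from . import fitness, microhabitat, ptr as ptr_mod
from .core import bootstrap_thermoreg, compute_deviation_set
from .types import (
    MICROHABITATS,
    OperativeRecord,
    PreferredRange,
    SelectedTemperature,
    TemperatureRecord,
)

log = logging.getLogger(__name__)

__all__ = [
    "CAPTURE_COLUMNS",
    "SELECTED_COLUMNS",
    "LOGGER_COLUMNS",
    "read_capture_csv",
    "write_capture_csv",
    "read_selected_csv",
    "write_selected_csv",
    "read_logger_csv",
    "write_logger_csv",
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
]

CAPTURE_COLUMNS = [
    "lizard_id", "sex", "svl_mm", "mass_g", "date", "time_gmt", "era",
    "t_b", "t_a", "t_s",
]
CAPTURE_MANDATORY = ["lizard_id", "sex", "date", "time_gmt", "era", "t_b"]
SELECTED_COLUMNS = ["lizard_id", "sex", "hour_gmt", "t_sel"]
LOGGER_COLUMNS = ["model_id", "microhabitat", "date", "time_gmt", "t_e"]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _opt_float(s: Optional[str]) -> Optional[float]:
    if s is None or s == "" or s != s:  # NaN-safe
        return None
    return float(s)


def _read_rows(path, mandatory: Sequence[str], all_columns: Sequence[str]):
    """Yield (line_number, row dict) from a headered CSV, validating
    the header against the mandatory columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header row")
        for col in mandatory:
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: missing mandatory column {col!r}")
        rows = [(i, row) for i, row in enumerate(reader, start=2)]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def read_capture_csv(path) -> List[TemperatureRecord]:
    """Parse field capture records; malformed rows are skipped and
    logged with their line numbers."""
    records, bad = [], []
    for lineno, row in _read_rows(path, CAPTURE_MANDATORY, CAPTURE_COLUMNS):
        try:
            records.append(
                TemperatureRecord(
                    lizard_id=row["lizard_id"],
                    sex=row["sex"],
                    svl=_opt_float(row.get("svl_mm")),
                    mass=_opt_float(row.get("mass_g")),
                    date=datetime.date.fromisoformat(row["date"]),
                    time=float(row["time_gmt"]),
                    era=row["era"],
                    t_b=float(row["t_b"]),
                    t_a=_opt_float(row.get("t_a")),
                    t_s=_opt_float(row.get("t_s")),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(lineno)
            log.warning("%s line %d rejected: %s", path, lineno, exc)
    if bad:
        log.warning("%s: rejected %d malformed rows (lines %s)", path, len(bad), bad)
    if not records:
        raise ValueError(f"{path}: no valid capture records")
    return records


def write_capture_csv(records: Sequence[TemperatureRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CAPTURE_COLUMNS)
        for r in records:
            w.writerow(
                [r.lizard_id, r.sex, _fmt(r.svl), _fmt(r.mass), r.date.isoformat(),
                 _fmt(r.time), r.era, _fmt(r.t_b), _fmt(r.t_a), _fmt(r.t_s)]
            )


def read_selected_csv(path) -> List[SelectedTemperature]:
    records, bad = [], []
    for lineno, row in _read_rows(path, SELECTED_COLUMNS, SELECTED_COLUMNS):
        try:
            records.append(
                SelectedTemperature(
                    lizard_id=row["lizard_id"],
                    sex=row["sex"],
                    hour=int(row["hour_gmt"]),
                    t_sel=float(row["t_sel"]),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append(lineno)
            log.warning("%s line %d rejected: %s", path, lineno, exc)
    if bad:
        log.warning("%s: rejected %d malformed rows (lines %s)", path, len(bad), bad)
    if not records:
        raise ValueError(f"{path}: no valid gradient selections")
    return records


def write_selected_csv(records: Sequence[SelectedTemperature], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SELECTED_COLUMNS)
        for r in records:
            w.writerow([r.lizard_id, r.sex, r.hour, _fmt(r.t_sel)])


def read_logger_csv(path, dialect: str = "long") -> List[OperativeRecord]:
    """Parse operative-temperature logger readings.

    ``dialect="long"`` expects one reading per row; ``dialect="wide"``
    expects ``date,time_gmt`` plus one ``<model_id>:<microhabitat>``
    column per copper model.  Unknown microhabitat labels are rejected
    row-wise (long) or at the header (wide) and logged.
    """
    if dialect == "long":
        records, bad = [], []
        for lineno, row in _read_rows(path, LOGGER_COLUMNS, LOGGER_COLUMNS):
            try:
                records.append(
                    OperativeRecord(
                        model_id=row["model_id"],
                        microhabitat=row["microhabitat"],
                        date=datetime.date.fromisoformat(row["date"]),
                        time=float(row["time_gmt"]),
                        t_e=float(row["t_e"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                bad.append(lineno)
                log.warning("%s line %d rejected: %s", path, lineno, exc)
        if bad:
            log.warning("%s: rejected %d malformed rows (lines %s)", path, len(bad), bad)
        if not records:
            raise ValueError(f"{path}: no valid logger readings")
        return records
    if dialect == "wide":
        return _read_logger_wide(path)
    raise ValueError(f"unknown logger dialect {dialect!r}")


def _read_logger_wide(path) -> List[OperativeRecord]:
    rows = _read_rows(path, ["date", "time_gmt"], None)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    model_cols = []
    for col in header:
        if col in ("date", "time_gmt"):
            continue
        if ":" not in col:
            raise ValueError(
                f"{path}: wide column {col!r} is not '<model_id>:<microhabitat>'"
            )
        model_id, micro = col.split(":", 1)
        if micro not in MICROHABITATS:
            log.warning("%s: column %r has unknown microhabitat; skipped", path, col)
            continue
        model_cols.append((col, model_id, micro))
    records, bad = [], []
    for lineno, row in rows:
        try:
            date = datetime.date.fromisoformat(row["date"])
            time = float(row["time_gmt"])
            for col, model_id, micro in model_cols:
                if row.get(col, "") == "":
                    continue
                records.append(
                    OperativeRecord(
                        model_id=model_id, microhabitat=micro,
                        date=date, time=time, t_e=float(row[col]),
                    )
                )
        except (ValueError, TypeError) as exc:
            bad.append(lineno)
            log.warning("%s line %d rejected: %s", path, lineno, exc)
    if bad:
        log.warning("%s: rejected %d malformed rows (lines %s)", path, len(bad), bad)
    if not records:
        raise ValueError(f"{path}: no valid logger readings")
    return records


def write_logger_csv(records: Sequence[OperativeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOGGER_COLUMNS)
        for r in records:
            w.writerow(
                [r.model_id, r.microhabitat, r.date.isoformat(), _fmt(r.time), _fmt(r.t_e)]
            )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full analysis run needs."""

    capture_csv: str
    selected_csv: str
    logger_csv: str
    outdir: str
    seed: int
    era_a: str = "1983-1989"
    era_b: str = "2012"
    central_fraction: float = 0.5
    n_resamples: int = 500
    activity_window: Tuple[int, int] = (9, 18)
    test_routing: Dict[str, str] = field(
        default_factory=lambda: dict(era_mod.DEFAULT_TEST_ROUTING)
    )
    suitability_criterion: str = "any_reading"
    logger_dialect: str = "long"
    t_opt: float = fitness.LACERTID_SPRINT_OPTIMUM.t_opt

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.activity_window = tuple(cfg.activity_window)
        return cfg


@dataclass
class ReportBundle:
    ptr: PreferredRange
    thermo: "object"              # ThermoregSummary
    profile: "object"             # MicrohabitatProfile
    suitability: "object"         # SuitabilityResult
    comparison: "object"          # MicrohabitatComparison
    era_report: "object"          # EraComparisonReport
    sex_pooling: tuple
    margins: Dict[str, float]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, datetime.date):
        return obj.isoformat()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    return obj


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run the complete analysis and write the report bundle.

    Stages: gradient selections -> PTR; 2012 captures + logger series
    -> d_b, d_e, bootstrap indices; logger series -> microhabitat
    profile, hourly suitability, microhabitat comparison; both eras ->
    warming contrast; era means -> safety margins.  Outputs land in
    ``cfg.outdir``: ``results.json`` (machine-readable, byte-stable for
    a fixed config and seed), ``era_means.csv`` and ``report.txt``.
    """
    for p in (cfg.capture_csv, cfg.selected_csv, cfg.logger_csv):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file missing before any computation: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage ptr: selections from %s, central fraction %s",
             cfg.selected_csv, cfg.central_fraction)
    selections = read_selected_csv(cfg.selected_csv)
    the_ptr = ptr_mod.compute_ptr(selections, cfg.central_fraction)

    log.info("stage captures: %s", cfg.capture_csv)
    captures = read_capture_csv(cfg.capture_csv)
    recs_a = [r for r in captures if r.era == cfg.era_a]
    recs_b = [r for r in captures if r.era == cfg.era_b]
    if not recs_a or not recs_b:
        raise ValueError(
            f"need captures for both eras {cfg.era_a!r} and {cfg.era_b!r}"
        )

    log.info("stage logger: %s (dialect %s)", cfg.logger_csv, cfg.logger_dialect)
    operative = read_logger_csv(cfg.logger_csv, dialect=cfg.logger_dialect)

    log.info("stage indices: bootstrap B=%d seed=%d", cfg.n_resamples, cfg.seed)
    db = compute_deviation_set([r.t_b for r in recs_b], the_ptr, source="body")
    de = microhabitat.thermal_quality(operative, the_ptr, hours=cfg.activity_window)
    thermo = bootstrap_thermoreg(db, de, cfg.n_resamples, seed=cfg.seed)

    log.info("stage microhabitat")
    profile = microhabitat.summarize_operative(operative, the_ptr, cfg.activity_window)
    suit = microhabitat.hourly_suitability(profile, criterion=cfg.suitability_criterion)
    comparison = microhabitat.compare_microhabitats(
        operative, the_ptr, cfg.activity_window
    )

    log.info("stage era comparison: %s vs %s", cfg.era_a, cfg.era_b)
    pooling = era_mod.sex_pooling_check(recs_b)
    report = era_mod.compare_eras(recs_a, recs_b, cfg.test_routing)

    opt = fitness.OptimalTemperature(t_opt=cfg.t_opt, se=0.0, source="config")
    margins = {
        "era_a": fitness.safety_margin(report.variables["t_b"].mean_a, opt),
        "era_b": fitness.safety_margin(report.variables["t_b"].mean_b, opt),
        "t_opt": cfg.t_opt,
    }

    bundle = ReportBundle(
        ptr=the_ptr, thermo=thermo, profile=profile, suitability=suit,
        comparison=comparison, era_report=report, sex_pooling=pooling,
        margins=margins,
    )
    _write_outputs(bundle, cfg, outdir)
    return bundle


def _write_outputs(bundle: ReportBundle, cfg: RunConfig, outdir: Path) -> None:
    payload = {
        "config": {
            "seed": cfg.seed,
            "n_resamples": cfg.n_resamples,
            "central_fraction": cfg.central_fraction,
            "activity_window": list(cfg.activity_window),
            "test_routing": cfg.test_routing,
            "suitability_criterion": cfg.suitability_criterion,
        },
        "ptr": _jsonable(bundle.ptr),
        "indices": _jsonable(bundle.thermo),
        "microhabitat": {
            "global_mean": bundle.profile.global_mean,
            "global_sd": bundle.profile.global_sd,
            "n_total": bundle.profile.n_total,
            "kruskal": _jsonable(bundle.comparison.kruskal),
            "nemenyi": _jsonable(bundle.comparison.nemenyi),
            "ranking": _jsonable(bundle.comparison.ranking),
            "suitability": _jsonable(bundle.suitability),
        },
        "era_comparison": _jsonable(bundle.era_report),
        "sex_pooling": {
            "test": _jsonable(bundle.sex_pooling[0]),
            "pool": bundle.sex_pooling[1],
        },
        "safety_margins": _jsonable(bundle.margins),
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    rows = []
    for var, c in bundle.era_report.variables.items():
        rows.append(
            {"variable": var,
             f"mean_{bundle.era_report.era_a}": round(c.mean_a, 2),
             f"se_{bundle.era_report.era_a}": round(c.se_a, 2),
             f"n_{bundle.era_report.era_a}": c.n_a,
             f"mean_{bundle.era_report.era_b}": round(c.mean_b, 2),
             f"se_{bundle.era_report.era_b}": round(c.se_b, 2),
             f"n_{bundle.era_report.era_b}": c.n_b,
             "delta": round(c.delta, 2)}
        )
    pd.DataFrame(rows).to_csv(outdir / "era_means.csv", index=False)

    t = bundle.thermo
    lines = [
        "Thermal-biology analysis report",
        "================================",
        f"PTR (central {bundle.ptr.central_fraction:.0%}): "
        f"[{bundle.ptr.lower:.2f}, {bundle.ptr.upper:.2f}] degC, "
        f"breadth {bundle.ptr.breadth:.2f} degC",
        f"accuracy mean d_b = {t.mean_db:.2f} +- {t.se_db:.3f} degC (n={t.n_body})",
        f"thermal quality mean d_e = {t.mean_de:.2f} +- {t.se_de:.3f} degC "
        f"(n={t.n_operative})",
        f"effectiveness E = {t.e_index:.2f} +- {t.se_e:.3f} "
        f"(bootstrap B={t.n_resamples}, seed={t.seed})",
        f"operative global mean = {bundle.profile.global_mean:.2f} +- "
        f"{bundle.profile.global_sd:.2f} degC (n={bundle.profile.n_total})",
        f"all activity hours offer a suitable patch: "
        f"{bundle.suitability.all_hours_covered}",
        f"safety margin {bundle.era_report.era_a}: {bundle.margins['era_a']:.2f} degC; "
        f"{bundle.era_report.era_b}: {bundle.margins['era_b']:.2f} degC "
        f"(t_opt = {bundle.margins['t_opt']:.2f} degC)",
    ]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    log.info("wrote %s", outdir / "results.json")
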