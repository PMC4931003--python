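#!/usr/bin/env python
"""Hertz thermoregulation indices with bootstrap uncertainty.

Scores present-day field body temperatures (accuracy, mean d_b) and
the operative-temperature series (habitat thermal quality, mean d_e)
against the PTR, and reports the effectiveness of thermoregulation
E = 1 - mean d_b / mean d_e with standard errors from 500 bootstrap
resamples.  Writes results/indices.json.
"""

import argparse
import json
from pathlib import Path

from thermoreg import bootstrap_thermoreg, compute_deviation_set, compute_ptr, thermal_quality
from thermoreg.io import read_capture_csv, read_logger_csv, read_selected_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--era", default="2012")
    ap.add_argument("--n-resamples", type=int, default=500)
    args = ap.parse_args()
    data = args.outdir / "data"
    if not (data / "logger.csv").exists():
        raise SystemExit(f"{data} incomplete; run 01_simulate_data.py first")

    ptr = compute_ptr(read_selected_csv(data / "selected.csv"))
    records = [r for r in read_capture_csv(data / "captures.csv") if r.era == args.era]
    ops = read_logger_csv(data / "logger.csv")

    db = compute_deviation_set([r.t_b for r in records], ptr, source="body")
    de = thermal_quality(ops, ptr)
    s = bootstrap_thermoreg(db, de, args.n_resamples, seed=args.seed)

    print(f"PTR [{ptr.lower:.2f}, {ptr.upper:.2f}] degC")
    print(f"accuracy of thermoregulation  mean d_b = {s.mean_db:.2f} +- {s.se_db:.3f} degC  (n = {s.n_body})")
    print(f"thermal quality of habitat    mean d_e = {s.mean_de:.2f} +- {s.se_de:.3f} degC  (n = {s.n_operative})")
    print(f"effectiveness                 E = {s.e_index:.2f} +- {s.se_e:.3f}  (B = {s.n_resamples})")
    if s.e_index > 0.7:
        print("-> an effective thermoregulator in a thermally poor habitat")

    out = args.outdir / "indices.json"
    out.write_text(json.dumps({
        "mean_db": round(s.mean_db, 4), "se_db": round(s.se_db, 4),
        "mean_de": round(s.mean_de, 4), "se_de": round(s.se_de, 4),
        "e_index": round(s.e_index, 4), "se_e": round(s.se_e, 4),
        "n_body": s.n_body, "n_operative": s.n_operative,
        "n_resamples": s.n_resamples, "seed": s.seed,
    }, indent=2) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
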