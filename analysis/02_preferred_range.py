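#!/usr/bin/env python
"""Estimate the preferred temperature range (PTR) from the gradient
selections and report the precision of thermoregulation (breadth).

Reads results/data/selected.csv (run 01_simulate_data.py first) and
writes results/ptr.json.
"""

import argparse
import json
from pathlib import Path

from thermoreg import compute_ptr
from thermoreg.io import read_selected_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--central-fraction", type=float, default=0.5)
    args = ap.parse_args()
    selected_csv = args.outdir / "data" / "selected.csv"
    if not selected_csv.exists():
        raise SystemExit(f"{selected_csv} not found; run 01_simulate_data.py first")

    sel = read_selected_csv(selected_csv)
    ptr = compute_ptr(sel, args.central_fraction)
    print(
        f"PTR (central {ptr.central_fraction:.0%} of {len(sel)} selections): "
        f"[{ptr.lower:.2f}, {ptr.upper:.2f}] degC"
    )
    print(f"precision of thermoregulation (breadth): {ptr.breadth:.2f} degC")
    out = args.outdir / "ptr.json"
    out.write_text(json.dumps({
        "lower": round(ptr.lower, 4), "upper": round(ptr.upper, 4),
        "breadth": round(ptr.breadth, 4),
        "central_fraction": ptr.central_fraction, "n": len(sel),
    }, indent=2) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
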