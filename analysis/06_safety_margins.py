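#!/usr/bin/env python
"""Thermal safety margins and the illustrative performance-curve figure.

Computes the margin between each era's mean body temperature and the
lacertid sprint-performance optimum (34.53 degC) and draws the
left-skewed performance curve with both era means marked.  Writes
results/safety_margins.json and results/figures/performance_curve.png.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from thermoreg import LACERTID_SPRINT_OPTIMUM, safety_margin, skewed_performance_curve
from thermoreg.io import read_capture_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--era-a", default="1983-1989")
    ap.add_argument("--era-b", default="2012")
    args = ap.parse_args()
    captures_csv = args.outdir / "data" / "captures.csv"
    if not captures_csv.exists():
        raise SystemExit(f"{captures_csv} not found; run 01_simulate_data.py first")

    captures = read_capture_csv(captures_csv)
    means = {}
    for era in (args.era_a, args.era_b):
        tb = [r.t_b for r in captures if r.era == era]
        means[era] = float(np.mean(tb))

    opt = LACERTID_SPRINT_OPTIMUM
    margins = {era: safety_margin(m, opt) for era, m in means.items()}
    print(f"performance optimum: {opt.t_opt:.2f} +- {opt.se:.2f} degC ({opt.source})")
    for era in (args.era_a, args.era_b):
        print(f"{era}: mean T_b = {means[era]:.2f} degC -> "
              f"safety margin {margins[era]:.2f} degC below the optimum")
    print("-> warming so far moved body temperatures toward, not past, the "
          "optimum; overshooting it would cost fitness steeply (left skew)")

    out = args.outdir / "safety_margins.json"
    out.write_text(json.dumps(
        {"t_opt": opt.t_opt,
         **{era: {"mean_tb": round(means[era], 4), "margin": round(margins[era], 4)}
            for era in means}},
        indent=2) + "\n")
    print(f"-> {out}")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = args.outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    t = np.linspace(0.0, 46.0, 1000)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, skewed_performance_curve(t), color="black",
            label="illustrative performance curve")
    ax.axvline(opt.t_opt, ls=":", color="grey", label=f"optimum {opt.t_opt:.1f} degC")
    for era, style in zip(means, ("--", "-.")):
        ax.axvline(means[era], ls=style, label=f"mean T_b {era}: {means[era]:.1f} degC")
    ax.set_xlabel("body temperature (degC)")
    ax.set_ylabel("relative performance")
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    fig.savefig(figdir / "performance_curve.png", dpi=150)
    print(f"-> {figdir / 'performance_curve.png'}")


if __name__ == "__main__":
    main()
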