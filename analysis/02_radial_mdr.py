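#!/usr/bin/env python
"""Radial-distribution contrast: control vs perinuclear-shifted cells.

Runs the full two-condition experiment — 30 cells per condition, gaussian
radial laws with the knockdown-like condition shifted 10 normalized units
inward — and reports per-cell MDR, the mean radial profiles, and the
Mann–Whitney comparison.  Writes cells.csv / profile.csv / stats.json under
results/radial/.
"""

import json
from pathlib import Path

from mitomorph.pipeline import run_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "radial"


def main() -> None:
    config = {
        "seed": 1,
        "conditions": [
            {
                "label": label,
                "n_cells": 30,
                "scene2d": {
                    "radial_law": {"kind": "gaussian", "mu": mu, "sigma": 8},
                    "n_objects": 300,
                },
            }
            for label, mu in (("control", 65.0), ("knockdown", 55.0))
        ],
        "endpoints": ["mdr", "morphology"],
    }
    report = run_experiment(config, OUT)
    cmp = report["comparisons"]["mdr"]
    g = cmp["groups"]
    print("per-cell mean distribution radius (MDR, % of normalized axis):")
    for label in ("control", "knockdown"):
        s = g[label]
        print(f"  {label:10s} {s['mean']:.2f} ± {s['sem']:.2f} (n={s['n']})")
    print(f"Mann–Whitney U = {cmp['statistic']:.0f}, p = {cmp['p_value']:.2e}")
    print("the knockdown-like condition is shifted perinuclearly, as generated")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
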