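#!/usr/bin/env python
"""Optimal risk cut-points per pain region, by two rules.

From the per-cohort analysis reports: the full sensitivity/specificity/
Youden-J table over cut-points 1..8 for every region, the cut-point
maximising Youden's J, and the best cut-point keeping specificity >= 0.7
(false-positive rate < 30%).  Shows whether a single cut-point can serve
all regions and services.
"""

import argparse
from pathlib import Path

from mskscreen.pipeline import cutpoint_frame, load_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    chosen = {}
    for name in ("cohort1", "cohort2"):
        report = load_report(args.outdir / f"report_{name}.json")
        table = cutpoint_frame(report)
        table.to_csv(args.outdir / f"cutpoints_{name}.csv", index=False)
        print(f"\n{name}: selected cut-points (positive iff score >= cut)")
        for region, block in report["regions"].items():
            y, c = block["selected_youden"], block["selected_constrained"]
            chosen.setdefault(name, set()).add((y, c))
            print(
                f"  {region:<11} Youden's J -> {y}   "
                f"specificity>=0.7 -> {c if c is not None else 'infeasible'}"
            )
    consistent = all(len(v) == 1 for v in chosen.values())
    print(
        "\nA single cut-point "
        + ("would" if consistent else "would NOT")
        + " serve all pain regions within each service."
    )


if __name__ == "__main__":
    main()
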