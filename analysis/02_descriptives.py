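#!/usr/bin/env python
"""Cohort descriptives: score distribution, floor/ceiling effects,
region mix and 6-month outcome prevalence.

Reads the simulated cohorts from results/, applies complete-case
preparation, and writes a JSON summary per cohort.  A floor or ceiling
effect is reported when >10% of patients sit at score 0 or 8.
"""

import argparse
import json
from pathlib import Path

from mskscreen.descriptives import cohort_summary
from mskscreen.io import prepare_cohort, read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = {}
    for name in ("cohort1", "cohort2"):
        frame = read_cohort(args.outdir / f"{name}.csv")
        analysed, log = prepare_cohort(frame)
        s = cohort_summary(analysed)
        out[name] = s.to_dict()
        flags = []
        if s.floor_flag:
            flags.append("floor effect")
        if s.ceiling_flag:
            flags.append("ceiling effect")
        print(
            f"{name}: n={s.n} (excluded {log.n_excluded}), "
            f"score {s.score_mean:.2f} (SD {s.score_sd:.2f}), "
            f"floor {s.floor_pct:.1f}% / ceiling {s.ceiling_pct:.1f}% "
            f"[{', '.join(flags) or 'no floor/ceiling effect'}], "
            f"poor outcome {s.poor_outcome_pct:.1f}%"
        )

    path = args.outdir / "descriptives.json"
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
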