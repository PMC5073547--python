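"""Cohort-level descriptive statistics: score distribution, floor/ceiling
effects, region mix, outcome prevalence.

A floor (ceiling) effect is flagged when strictly more than 10% of the
cohort sits at the minimum (maximum) possible score — the usual criterion
for limited measurement range of a patient-reported instrument.  Standard
deviations are sample SDs (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import N_ITEMS, POOR_OUTCOME_PCS_MAX, REGIONS

FLOOR_CEILING_PCT_THRESHOLD = 10.0  # strict: exactly 10% is not flagged


@dataclass
class DescriptiveSummary:
    n: int
    score_mean: float
    score_sd: float
    floor_pct: float
    ceiling_pct: float
    floor_flag: bool
    ceiling_flag: bool
    region_pct: dict[str, float] = field(default_factory=dict)
    poor_outcome_pct: float | None = None
    pcs_mean: float | None = None
    pcs_sd: float | None = None
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "floor_pct": self.floor_pct,
            "ceiling_pct": self.ceiling_pct,
            "floor_flag": self.floor_flag,
            "ceiling_flag": self.ceiling_flag,
            "region_pct": dict(self.region_pct),
            "poor_outcome_pct": self.poor_outcome_pct,
            "pcs_mean": self.pcs_mean,
            "pcs_sd": self.pcs_sd,
            "n_excluded": self.n_excluded,
        }


def flag_floor_ceiling(floor_pct: float, ceiling_pct: float) -> tuple[bool, bool]:
    """Apply the >10% rule (strict inequality) to floor/ceiling percentages."""
    return (
        floor_pct > FLOOR_CEILING_PCT_THRESHOLD,
        ceiling_pct > FLOOR_CEILING_PCT_THRESHOLD,
    )


def score_distribution_summary(scores) -> DescriptiveSummary:
    """Mean, sample SD and floor/ceiling percentages of the 0-8 tool score."""
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("need a non-empty 1-D score vector")
    if ((s < 0) | (s > N_ITEMS) | (s != np.round(s))).any():
        raise ValueError(f"scores must be integers in [0, {N_ITEMS}]")
    floor_pct = float((s == 0).mean() * 100.0)
    ceiling_pct = float((s == N_ITEMS).mean() * 100.0)
    floor_flag, ceiling_flag = flag_floor_ceiling(floor_pct, ceiling_pct)
    return DescriptiveSummary(
        n=int(s.size),
        score_mean=float(s.mean()),
        score_sd=float(s.std(ddof=1)) if s.size > 1 else 0.0,
        floor_pct=floor_pct,
        ceiling_pct=ceiling_pct,
        floor_flag=floor_flag,
        ceiling_flag=ceiling_flag,
    )


def cohort_summary(cohort: pd.DataFrame) -> DescriptiveSummary:
    """Full descriptive summary of a scored cohort frame.

    ``cohort`` must carry columns ``score``, ``region`` and ``pcs_6m``
    (see :mod:`mskscreen.io`).  Records with a missing score or outcome are
    excluded (complete-case) and counted in ``n_excluded``.
    """
    required = {"score", "region", "pcs_6m"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort frame lacks columns: {sorted(missing)}")
    complete = cohort.dropna(subset=["score", "pcs_6m"])
    n_excluded = len(cohort) - len(complete)
    if len(complete) == 0:
        raise ValueError("no complete records (score + outcome) in the cohort")
    summary = score_distribution_summary(complete["score"].to_numpy())
    summary.n_excluded = n_excluded
    counts = complete["region"].value_counts()
    summary.region_pct = {
        r: float(counts.get(r, 0) / len(complete) * 100.0) for r in REGIONS
    }
    pcs = complete["pcs_6m"].to_numpy(dtype=float)
    summary.poor_outcome_pct = float((pcs <= POOR_OUTCOME_PCS_MAX).mean() * 100.0)
    summary.pcs_mean = float(pcs.mean())
    summary.pcs_sd = float(pcs.std(ddof=1)) if pcs.size > 1 else 0.0
    return summary
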