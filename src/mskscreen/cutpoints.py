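"""Sensitivity/specificity tables over candidate cut-points and optimal
cut-point selection.

Two selection rules are provided:

* **Youden's J**: J = sensitivity + specificity - 1, maximised over
  cut-points; the standard compromise when false negatives and false
  positives are weighted equally.
* **Specificity floor**: among cut-points keeping specificity >= a floor
  (default 0.7, i.e. false-positive rate < 30%), maximise J — or,
  optionally, maximise sensitivity.  The floor encodes the a-priori
  clinical rule that overtreating more than 30% of the good-outcome
  patients is unacceptable.

Ties on the objective are broken toward the *lower* cut-point (higher
sensitivity): a screening tool prefers to miss fewer poor-outcome
patients.  Candidate cut-points default to 1..8 — at c the test is
positive iff score >= c; c=0 (everyone positive) and c=9 (no one
positive) are degenerate and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

DEFAULT_CUTPOINTS: tuple[int, ...] = tuple(range(1, 9))
DEFAULT_SPECIFICITY_FLOOR = 0.7


def sens_spec_table(
    scores, outcomes, cutpoints: Iterable[int] = DEFAULT_CUTPOINTS
) -> pd.DataFrame:
    """One row per candidate cut-point c: sensitivity, specificity, Youden's J.

    sensitivity(c) = P(score >= c | poor outcome)
    specificity(c) = P(score <  c | not poor)
    youden_j(c)    = sensitivity + specificity - 1

    Requires at least one case and one control.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-D arrays")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary (1 = poor outcome)")
    cases = s[y == 1]
    controls = s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError(
            "sensitivity/specificity undefined: need both outcome classes "
            f"(got {cases.size} cases, {controls.size} controls)"
        )
    cuts = np.asarray(list(cutpoints), dtype=float)
    if cuts.size == 0:
        raise ValueError("empty cut-point candidate set")
    sens = (cases[None, :] >= cuts[:, None]).mean(axis=1)
    spec = (controls[None, :] < cuts[:, None]).mean(axis=1)
    return pd.DataFrame(
        {
            "cutpoint": np.asarray(list(cutpoints)),
            "sensitivity": sens,
            "specificity": spec,
            "youden_j": sens + spec - 1.0,
        }
    )


_TIE_TOL = 1e-12  # J values this close are ties (guards float summation noise)


def _argbest(t: pd.DataFrame, col: str):
    """Lowest cut-point whose objective is within _TIE_TOL of the maximum."""
    best = t[col].max()
    tied = t[t[col] >= best - _TIE_TOL]
    cp = tied["cutpoint"].min()
    return cp.item() if hasattr(cp, "item") else cp


def select_youden(table: pd.DataFrame):
    """Cut-point with maximal Youden's J; ties go to the lower cut-point."""
    if len(table) == 0:
        raise ValueError("empty cut-point table")
    return _argbest(table, "youden_j")


def select_constrained(
    table: pd.DataFrame,
    floor: float = DEFAULT_SPECIFICITY_FLOOR,
    objective: Literal["youden", "sensitivity"] = "youden",
):
    """Best cut-point subject to specificity >= floor; None if infeasible.

    By default maximises Youden's J among the feasible rows; with
    ``objective="sensitivity"`` maximises sensitivity instead.  Ties break
    toward the lower cut-point.
    """
    if len(table) == 0:
        raise ValueError("empty cut-point table")
    if not 0.0 < floor < 1.0:
        raise ValueError(f"specificity floor must lie in (0, 1), got {floor}")
    if objective not in ("youden", "sensitivity"):
        raise ValueError(f"unknown objective {objective!r}")
    feasible = table[table["specificity"] >= floor]
    if len(feasible) == 0:
        return None
    col = "youden_j" if objective == "youden" else "sensitivity"
    return _argbest(feasible, col)


@dataclass(frozen=True)
class CutpointTable:
    """Per-group cut-point table with both selections attached."""

    rows: pd.DataFrame
    selected_youden: int
    selected_constrained: int | None
    specificity_floor: float = DEFAULT_SPECIFICITY_FLOOR

    @classmethod
    def from_scores(
        cls,
        scores,
        outcomes,
        cutpoints: Iterable[int] = DEFAULT_CUTPOINTS,
        floor: float = DEFAULT_SPECIFICITY_FLOOR,
        objective: Literal["youden", "sensitivity"] = "youden",
    ) -> "CutpointTable":
        rows = sens_spec_table(scores, outcomes, cutpoints)
        return cls(
            rows=rows,
            selected_youden=int(select_youden(rows)),
            selected_constrained=(
                None
                if (sel := select_constrained(rows, floor, objective)) is None
                else int(sel)
            ),
            specificity_floor=floor,
        )
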