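"""Empirical ROC curves, Mann-Whitney AUC, DeLong variance, and a
chi-square test of AUC equality across independent groups.

Conventions
-----------
* Cases are patients with the poor outcome; higher scores indicate worse
  prognosis.
* A patient is test-positive at threshold c iff score >= c.
* Tied case-control score pairs receive 0.5 credit (Mann-Whitney), and the
  same convention is used in the DeLong placement values, so the pairwise
  AUC, the trapezoidal ROC area and the variance estimator are mutually
  consistent.

The equality test treats the groups as disjoint patient sets (pain
regions), so the group AUCs are independent and no covariance terms
arise:

    Q = sum_i w_i (A_i - A_bar)^2,   w_i = 1 / var_i,
    A_bar = sum_i w_i A_i / sum_i w_i,       Q ~ chi2(k - 1) under H0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class UndefinedAUCError(ValueError):
    """AUC (or its variance) is undefined for the given outcome split."""


def _split_cases_controls(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-D arrays")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcomes must be binary (1 = poor outcome)")
    cases = s[y == 1]
    controls = s[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise UndefinedAUCError(
            "AUC undefined: need at least one case and one control "
            f"(got {cases.size} cases, {controls.size} controls)"
        )
    return cases, controls


def _case_placements(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Placement value of each case: fraction of controls it beats (ties 0.5)."""
    sorted_controls = np.sort(controls)
    below = np.searchsorted(sorted_controls, cases, side="left")
    below_or_eq = np.searchsorted(sorted_controls, cases, side="right")
    return (below + 0.5 * (below_or_eq - below)) / controls.size


def auc_empirical(scores, outcomes) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 0.5 P(tie).

    Computed in O((m+n) log(m+n)) via placement values rather than by
    enumerating all case-control pairs.
    """
    cases, controls = _split_cases_controls(scores, outcomes)
    return float(_case_placements(cases, controls).mean())


def delong_variance(scores, outcomes) -> float:
    """DeLong structural-components variance of the empirical AUC.

    var = S10 / m + S01 / n, where S10 (S01) is the sample variance of the
    case (control) placement values and m, n are the group sizes.  Requires
    at least two cases and two controls; exactly zero under perfect
    separation.
    """
    cases, controls = _split_cases_controls(scores, outcomes)
    m, n = cases.size, controls.size
    if m < 2 or n < 2:
        raise UndefinedAUCError(
            f"variance undefined: need >=2 cases and >=2 controls (got {m}, {n})"
        )
    v10 = _case_placements(cases, controls)          # per-case
    v01 = 1.0 - _case_placements(controls, cases)    # per-control
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return float(s10 / m + s01 / n)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC and DeLong variance."""

    thresholds: np.ndarray            # candidate cuts, ascending
    fpr: np.ndarray                   # non-decreasing, starts 0 ends 1
    tpr: np.ndarray                   # non-decreasing, starts 0 ends 1
    auc: float
    auc_variance: float | None
    n_cases: int
    n_controls: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval AUC +/- z * sqrt(var), truncated to [0, 1]."""
        if self.auc_variance is None:
            raise UndefinedAUCError("no variance available for a confidence interval")
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(self.auc_variance)
        return (max(0.0, self.auc - half), min(1.0, self.auc + half))


def roc_points(scores, outcomes, with_variance: bool = True) -> RocResult:
    """Empirical ROC curve: one operating point per candidate cut.

    Candidate cuts are the distinct observed scores; at cut c a patient is
    positive iff score >= c.  The curve is anchored at (0, 0) (cut above
    the maximum) and (1, 1) (cut at/below the minimum).  Its trapezoidal
    area equals the Mann-Whitney AUC.
    """
    cases, controls = _split_cases_controls(scores, outcomes)
    thresholds = np.unique(np.concatenate([cases, controls]))
    m, n = cases.size, controls.size
    # positive iff score >= c  =>  tpr(c) = #cases >= c / m
    sorted_cases = np.sort(cases)
    sorted_controls = np.sort(controls)
    tpr = 1.0 - np.searchsorted(sorted_cases, thresholds, side="left") / m
    fpr = 1.0 - np.searchsorted(sorted_controls, thresholds, side="left") / n
    # ascending threshold gives descending rates; order points from (0,0) up
    fpr_curve = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr_curve = np.concatenate([[0.0], tpr[::-1], [1.0]])
    auc = float(np.trapezoid(tpr_curve, fpr_curve))
    var = None
    if with_variance and m >= 2 and n >= 2:
        var = delong_variance(scores, outcomes)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr_curve,
        tpr=tpr_curve,
        auc=auc,
        auc_variance=var,
        n_cases=m,
        n_controls=n,
    )


@dataclass(frozen=True)
class AucComparison:
    """Chi-square test of AUC equality across independent groups."""

    labels: tuple[str, ...]
    aucs: np.ndarray
    variances: np.ndarray
    chi_square: float
    df: int
    p_value: float
    excluded: tuple[str, ...] = field(default_factory=tuple)
    """Zero-variance (perfectly separating) groups: they enter the test in
    the infinite-weight limit, pinning the weighted mean, rather than as
    finite inverse-variance terms."""


def compare_auc_groups(
    groups: Sequence[tuple], labels: Sequence[str] | None = None
) -> AucComparison:
    """Test H0: all group AUCs are equal, for disjoint patient groups.

    Each element of ``groups`` is a ``(scores, outcomes)`` pair.  Groups
    whose DeLong variance is exactly zero (perfect separation) have
    infinite inverse-variance weight; they are handled in the limit — the
    weighted mean is pinned at their AUC — with a warning.
    """
    if labels is None:
        labels = [f"group_{i}" for i in range(len(groups))]
    labels = [str(lab) for lab in labels]
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    aucs, variances = [], []
    for lab, (s, y) in zip(labels, groups):
        try:
            a = auc_empirical(s, y)
            v = delong_variance(s, y)
        except UndefinedAUCError as exc:
            raise UndefinedAUCError(f"group '{lab}': {exc}") from exc
        aucs.append(a)
        variances.append(v)
    aucs = np.array(aucs)
    variances = np.array(variances)

    usable = variances > 0.0
    excluded = tuple(lab for lab, ok in zip(labels, usable) if not ok)
    df = len(groups) - 1
    if excluded:
        # Perfectly separating groups have zero estimated variance, i.e.
        # infinite weight: in the limit they pin the weighted mean at their
        # own AUC instead of contributing a finite term to Q.
        warnings.warn(
            "groups with zero DeLong variance (perfect separation) pin the "
            f"weighted mean in the AUC equality test: {', '.join(excluded)}",
            stacklevel=2,
        )
        pinned = aucs[~usable]
        if not np.allclose(pinned, pinned[0], atol=1e-12) or (
            usable.sum() == 0 and np.ptp(pinned) > 1e-12
        ):
            chi_square, p_value = float("inf"), 0.0
            return AucComparison(
                labels=tuple(labels), aucs=aucs, variances=variances,
                chi_square=chi_square, df=df, p_value=p_value, excluded=excluded,
            )
        a_bar = float(pinned[0])
        if usable.sum() == 0:
            chi_square = 0.0
        else:
            w = 1.0 / variances[usable]
            chi_square = float(np.sum(w * (aucs[usable] - a_bar) ** 2))
    else:
        w = 1.0 / variances
        a_bar = float(np.sum(w * aucs) / np.sum(w))
        chi_square = float(np.sum(w * (aucs - a_bar) ** 2))
    p_value = float(stats.chi2.sf(chi_square, df))
    return AucComparison(
        labels=tuple(labels),
        aucs=aucs,
        variances=variances,
        chi_square=chi_square,
        df=df,
        p_value=p_value,
        excluded=excluded,
    )
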