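"""End-to-end cohort analysis: descriptives, per-region ROC/AUC with the
equality test, and cut-point tables, assembled into one report.

The report is JSON-canonical; CSV and markdown renderers reshape it for
reading.  Regions lacking both outcome classes (or with fewer than two
cases/controls for the variance) are listed in the exclusion notes
rather than in the per-region sections, and the equality test runs over
the remaining regions when at least two are usable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .cutpoints import DEFAULT_CUTPOINTS, DEFAULT_SPECIFICITY_FLOOR, CutpointTable
from .descriptives import cohort_summary
from .io import ExclusionLog, prepare_cohort
from .roc import UndefinedAUCError, compare_auc_groups, roc_points
from .scoring import REGIONS


def run_analysis(
    cohort: pd.DataFrame,
    item_columns: dict[str, str] | None = None,
    profile=None,
    specificity_floor: float = DEFAULT_SPECIFICITY_FLOOR,
    constrained_objective: Literal["youden", "sensitivity"] = "youden",
    cutpoints=DEFAULT_CUTPOINTS,
    metadata: dict | None = None,
) -> dict:
    """Run the full analysis on a raw cohort frame; returns the report dict."""
    analysed, log = prepare_cohort(cohort, item_columns=item_columns, profile=profile)
    if len(analysed) == 0:
        raise ValueError("no usable records after exclusions; nothing to analyse")
    return analyse_prepared(
        analysed,
        exclusions=log,
        specificity_floor=specificity_floor,
        constrained_objective=constrained_objective,
        cutpoints=cutpoints,
        metadata=metadata,
    )


def analyse_prepared(
    analysed: pd.DataFrame,
    exclusions: ExclusionLog | None = None,
    specificity_floor: float = DEFAULT_SPECIFICITY_FLOOR,
    constrained_objective: Literal["youden", "sensitivity"] = "youden",
    cutpoints=DEFAULT_CUTPOINTS,
    metadata: dict | None = None,
) -> dict:
    """Assemble the report from a frame that already has score/poor columns."""
    report: dict = {
        "mskscreen_version": __version__,
        "metadata": metadata or {},
        "descriptives": cohort_summary(analysed).to_dict(),
        "regions": {},
        "auc_comparison": None,
        "notes": [],
        "exclusions": exclusions.to_dict() if exclusions else None,
    }

    usable: list[tuple[str, np.ndarray, np.ndarray]] = []
    for region in REGIONS:
        sub = analysed[analysed["region"] == region]
        if len(sub) == 0:
            continue
        scores = sub["score"].to_numpy(dtype=float)
        poor = sub["poor"].to_numpy(dtype=int)
        n_cases = int(poor.sum())
        n_controls = int(len(poor) - n_cases)
        if n_cases < 2 or n_controls < 2:
            report["notes"].append(
                f"region '{region}' skipped: needs >=2 cases and >=2 controls "
                f"(has {n_cases}/{n_controls})"
            )
            continue
        roc = roc_points(scores, poor)
        ci_low, ci_high = roc.ci()
        table = CutpointTable.from_scores(
            scores,
            poor,
            cutpoints=cutpoints,
            floor=specificity_floor,
            objective=constrained_objective,
        )
        if table.selected_constrained is None:
            report["notes"].append(
                f"region '{region}': no cut-point satisfies specificity >= "
                f"{specificity_floor}"
            )
        report["regions"][region] = {
            "n": int(len(sub)),
            "n_poor": n_cases,
            "auc": roc.auc,
            "auc_variance": roc.auc_variance,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "roc_fpr": roc.fpr.tolist(),
            "roc_tpr": roc.tpr.tolist(),
            "cutpoint_table": table.rows.to_dict(orient="records"),
            "selected_youden": table.selected_youden,
            "selected_constrained": table.selected_constrained,
            "specificity_floor": specificity_floor,
        }
        usable.append((region, scores, poor))

    if len(usable) >= 2:
        try:
            cmp_ = compare_auc_groups(
                [(s, y) for _, s, y in usable], labels=[r for r, _, _ in usable]
            )
            report["auc_comparison"] = {
                "regions": list(cmp_.labels),
                "aucs": cmp_.aucs.tolist(),
                "chi_square": cmp_.chi_square,
                "df": cmp_.df,
                "p_value": cmp_.p_value,
                "excluded": list(cmp_.excluded),
            }
        except UndefinedAUCError as exc:
            report["notes"].append(f"AUC equality test omitted: {exc}")
    else:
        report["notes"].append(
            "AUC equality test omitted: fewer than two usable regions"
        )
    return report


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def cutpoint_frame(report: dict) -> pd.DataFrame:
    """Region x cut-point long table (the published Table-1 layout)."""
    rows = []
    for region, block in report["regions"].items():
        for rec in block["cutpoint_table"]:
            rows.append(
                {
                    "region": region,
                    "cutpoint": rec["cutpoint"],
                    "sensitivity": rec["sensitivity"],
                    "specificity": rec["specificity"],
                    "youden_j": rec["youden_j"],
                    "selected_youden": rec["cutpoint"] == block["selected_youden"],
                    "selected_constrained": rec["cutpoint"] == block["selected_constrained"],
                }
            )
    return pd.DataFrame(rows)


def auc_frame(report: dict) -> pd.DataFrame:
    """Per-region AUC summary (the ROC-figure caption layout)."""
    rows = []
    for region, block in report["regions"].items():
        rows.append(
            {
                "region": region,
                "n": block["n"],
                "n_poor": block["n_poor"],
                "auc": block["auc"],
                "ci_low": block["ci_low"],
                "ci_high": block["ci_high"],
            }
        )
    return pd.DataFrame(rows)


def render_markdown(report: dict) -> str:
    """Human-readable report: descriptives, AUC table, cut-point table."""
    d = report["descriptives"]
    lines = ["# Cohort analysis report", ""]
    meta = report.get("metadata") or {}
    if meta:
        lines += [f"*{k}: {v}*" for k, v in meta.items()] + [""]
    lines += [
        "## Descriptives",
        "",
        f"- n analysed: {d['n']} (excluded: {d['n_excluded']})",
        f"- score mean (SD): {d['score_mean']:.2f} ({d['score_sd']:.2f})",
        f"- floor {d['floor_pct']:.1f}% (flag: {d['floor_flag']}), "
        f"ceiling {d['ceiling_pct']:.1f}% (flag: {d['ceiling_flag']})",
        f"- poor 6-month outcome: {d['poor_outcome_pct']:.1f}%",
        f"- 6-month PCS mean (SD): {d['pcs_mean']:.1f} ({d['pcs_sd']:.1f})",
        "",
        "## Discrimination by pain region",
        "",
        "| region | n | n poor | AUC | 95% CI |",
        "|---|---|---|---|---|",
    ]
    for _, r in auc_frame(report).iterrows():
        lines.append(
            f"| {r['region']} | {r['n']} | {r['n_poor']} | {r['auc']:.3f} | "
            f"{r['ci_low']:.3f}-{r['ci_high']:.3f} |"
        )
    cmp_ = report.get("auc_comparison")
    if cmp_:
        lines += [
            "",
            f"AUC equality across regions: chi-square {cmp_['chi_square']:.3f} "
            f"on {cmp_['df']} df, p = {cmp_['p_value']:.3f}",
        ]
    lines += ["", "## Cut-points", ""]
    lines += [
        "| region | cut | sens | spec | J | Youden pick | floor pick |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in cutpoint_frame(report).iterrows():
        lines.append(
            f"| {r['region']} | {int(r['cutpoint'])} | {r['sensitivity']:.3f} | "
            f"{r['specificity']:.3f} | {r['youden_j']:.3f} | "
            f"{'*' if r['selected_youden'] else ''} | "
            f"{'*' if r['selected_constrained'] else ''} |"
        )
    notes = report.get("notes") or []
    if notes:
        lines += ["", "## Notes", ""] + [f"- {n}" for n in notes]
    return "\n".join(lines) + "\n"


def plot_roc(report: dict, path: str | Path) -> None:
    """Optional ROC figure, one curve per region (never an input to analysis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for region, block in report["regions"].items():
        ax.plot(
            block["roc_fpr"], block["roc_tpr"],
            label=f"{region} (AUC {block['auc']:.2f})", drawstyle="default",
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
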