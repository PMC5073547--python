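"""Cohort CSV schema, configuration files, and record preparation.

Canonical cohort schema — one row per patient:

    id, service, region, item_1 .. item_8, pcs_6m

``item_k`` columns hold 0/1 indicators in the fixed item order documented
in :data:`mskscreen.scoring.ITEM_NAMES` (item_1 = fear ... item_8 =
SF-12 bodily pain).  Alternatively a config may declare raw-response
columns per item plus positive-response sets; they are dichotomised on
load.  ``region`` uses the five lowercase tokens ``neck``, ``back``,
``upper_limb``, ``lower_limb``, ``multisite``.  ``pcs_6m`` is the
6-month SF-36 Physical Component Score in [0, 100], blank when lost to
follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scoring import (
    ITEM_NAMES,
    N_ITEMS,
    POOR_OUTCOME_PCS_MAX,
    REGIONS,
    MappingProfile,
    IncompleteRecordError,
    map_item_responses,
)

ITEM_COLUMNS = tuple(f"item_{k + 1}" for k in range(N_ITEMS))
REQUIRED_COLUMNS = ("id", "service", "region") + ITEM_COLUMNS + ("pcs_6m",)


class SchemaError(ValueError):
    """The cohort file violates the expected schema."""


@dataclass
class ExclusionLog:
    """Complete-case bookkeeping: why rows were dropped before analysis."""

    n_input: int = 0
    n_analysed: int = 0
    missing_items: int = 0
    missing_outcome: int = 0
    invalid_region: int = 0
    reasons: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_analysed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_analysed": self.n_analysed,
            "n_excluded": self.n_excluded,
            "missing_items": self.missing_items,
            "missing_outcome": self.missing_outcome,
            "invalid_region": self.invalid_region,
            "reasons": list(self.reasons),
        }


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON analysis config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_cohort(
    path: str | Path, item_columns: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a cohort CSV, checking the schema.

    ``item_columns`` optionally maps item names to raw-response column
    names (config-driven); when given, those columns replace the
    ``item_k`` requirement and are dichotomised later by
    :func:`prepare_cohort`.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    required = ["id", "service", "region", "pcs_6m"]
    if item_columns:
        unknown = set(item_columns) - set(ITEM_NAMES)
        if unknown:
            raise SchemaError(f"config names unknown items: {sorted(unknown)}")
        if set(item_columns) != set(ITEM_NAMES):
            raise SchemaError(
                f"config must map all {N_ITEMS} items; missing "
                f"{sorted(set(ITEM_NAMES) - set(item_columns))}"
            )
        required += list(item_columns.values())
    else:
        required += list(ITEM_COLUMNS)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file lacks required column(s): {missing}")
    return frame


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame to CSV in the canonical schema."""
    cols = [c for c in REQUIRED_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in cols]
    frame[cols + extra].to_csv(path, index=False)


def prepare_cohort(
    frame: pd.DataFrame,
    item_columns: dict[str, str] | None = None,
    profile: MappingProfile | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Score a raw cohort frame and apply complete-case exclusions.

    Returns the analysed frame with added ``score`` and ``poor`` columns,
    restricted to rows with all eight items, a valid region and a 6-month
    outcome; plus an :class:`ExclusionLog`.
    """
    log = ExclusionLog(n_input=len(frame))
    work = frame.copy()

    if item_columns:
        profile = profile or MappingProfile()
        indicators = np.full((len(work), N_ITEMS), np.nan)
        bad_rows = np.zeros(len(work), dtype=bool)
        for i, (_, row) in enumerate(work.iterrows()):
            raw = {item: row[col] for item, col in item_columns.items()}
            try:
                indicators[i] = map_item_responses(raw, profile)
            except IncompleteRecordError as exc:
                bad_rows[i] = True
                if len(log.reasons) < 50:
                    log.reasons.append(f"row {i} (id={row['id']}): {exc}")
        for k, col in enumerate(ITEM_COLUMNS):
            work[col] = indicators[:, k]
    else:
        for col in ITEM_COLUMNS:
            vals = pd.to_numeric(work[col], errors="coerce")
            ok = vals.isin([0.0, 1.0]) | vals.isna()
            if not ok.all():
                bad = work.loc[~ok, col].unique()[:5]
                raise SchemaError(f"column {col} has non-binary values, e.g. {list(bad)}")
            work[col] = vals

    item_mat = work[list(ITEM_COLUMNS)].to_numpy(dtype=float)
    has_items = ~np.isnan(item_mat).any(axis=1)
    log.missing_items = int((~has_items).sum())

    pcs = pd.to_numeric(work["pcs_6m"], errors="coerce").to_numpy(dtype=float)
    bad_pcs = (~np.isnan(pcs)) & ((pcs < 0) | (pcs > 100))
    if bad_pcs.any():
        raise SchemaError(
            f"pcs_6m outside [0, 100] in {int(bad_pcs.sum())} row(s), "
            f"e.g. {pcs[bad_pcs][:5].tolist()}"
        )
    has_outcome = ~np.isnan(pcs)
    log.missing_outcome = int((has_items & ~has_outcome).sum())

    valid_region = work["region"].isin(REGIONS).to_numpy()
    log.invalid_region = int((has_items & has_outcome & ~valid_region).sum())
    if log.invalid_region:
        bad = work.loc[~valid_region, "region"].unique()[:5]
        log.reasons.append(f"invalid region labels: {list(bad)}")

    keep = has_items & has_outcome & valid_region
    out = work.loc[keep].copy()
    out["score"] = item_mat[keep].sum(axis=1).astype(int)
    out["pcs_6m"] = pcs[keep]
    out["poor"] = (out["pcs_6m"] <= POOR_OUTCOME_PCS_MAX).astype(int)
    log.n_analysed = len(out)
    return out, log
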