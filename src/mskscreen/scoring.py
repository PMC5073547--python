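"""Scoring of the modified 8-item musculoskeletal screening tool.

The tool counts positive responses across eight binary items: five
psychosocial items (fear, catastrophising, anxiety, depression,
bothersomeness), two EQ-5D function items (problems walking about;
problems washing or dressing), and the SF-12 bodily-pain item.  The
total score ranges 0-8; scores of 0-3 classify a patient as low risk
and 4 or more as medium/high risk.

The 6-month physical-health outcome is the SF-36 Physical Component
Score (PCS, population-normalised 0-100) banded by tertiles: poor
(<=33), middle (>33 and <=66), good (>66).  "Poor outcome" is the
most severe band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

# Fixed item order; also the CSV column order (item_1 .. item_8).
ITEM_NAMES: tuple[str, ...] = (
    "fear",
    "catastrophising",
    "anxiety",
    "depression",
    "bothersomeness",
    "eq5d_walking",
    "eq5d_washing_dressing",
    "sf12_bodily_pain",
)

N_ITEMS = 8
LOW_RISK_MAX_SCORE = 3  # score <= 3 -> low risk; >= 4 -> medium/high
POOR_OUTCOME_PCS_MAX = 33.0
GOOD_OUTCOME_PCS_MIN = 66.0

REGIONS: tuple[str, ...] = ("neck", "back", "upper_limb", "lower_limb", "multisite")
SERVICES: tuple[str, ...] = ("physio_community", "interface_service", "other")


class RiskClass(str, Enum):
    LOW = "low"
    MEDIUM_HIGH = "medium_high"


class OutcomeBand(str, Enum):
    POOR = "poor"
    MIDDLE = "middle"
    GOOD = "good"


class IncompleteRecordError(ValueError):
    """A required item (or the outcome) is missing or unmappable."""

    def __init__(self, item: str, detail: str = "missing or unmappable"):
        self.item = item
        super().__init__(f"incomplete record: item '{item}' is {detail}")


# ---------------------------------------------------------------------------
# Response mapping
# ---------------------------------------------------------------------------

# Default positive-response sets for raw questionnaire text.  The five
# psychosocial items follow the original tool's convention: agree/disagree
# statements positive on "agree", bothersomeness positive for the top two
# categories.  EQ-5D items are yes/no; the SF-12 bodily-pain item is
# positive for the two most severe of its six levels.
DEFAULT_POSITIVE_RESPONSES: Mapping[str, frozenset[str]] = {
    "fear": frozenset({"agree"}),
    "catastrophising": frozenset({"agree"}),
    "anxiety": frozenset({"agree"}),
    "depression": frozenset({"agree"}),
    "bothersomeness": frozenset({"very much", "extremely"}),
    "eq5d_walking": frozenset({"yes"}),
    "eq5d_washing_dressing": frozenset({"yes"}),
    "sf12_bodily_pain": frozenset({"very severe", "extremely"}),
}

SF12_PAIN_LEVELS: tuple[str, ...] = (
    "none",
    "very mild",
    "mild",
    "moderate",
    "very severe",
    "extremely",
)


@dataclass(frozen=True)
class MappingProfile:
    """Positive-response sets used to dichotomise raw item responses.

    ``positive_responses`` maps each item name to the set of (lowercased,
    stripped) raw responses counted as positive.  Responses already coded
    0/1 (or the strings "0"/"1") pass through unchanged regardless of the
    profile.
    """

    positive_responses: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVE_RESPONSES)
    )

    def positive_set(self, item: str) -> frozenset[str]:
        try:
            return self.positive_responses[item]
        except KeyError:
            raise IncompleteRecordError(item, "not covered by the mapping profile")


DEFAULT_PROFILE = MappingProfile()


def _resolve_one(item: str, value, profile: MappingProfile) -> int:
    """Dichotomise a single raw or pre-coded item response."""
    if value is None:
        raise IncompleteRecordError(item)
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if isinstance(value, (int, np.integer)):
        if value in (0, 1):
            return int(value)
        raise IncompleteRecordError(item, f"numeric but not binary ({value!r})")
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            raise IncompleteRecordError(item)
        if value in (0.0, 1.0):
            return int(value)
        raise IncompleteRecordError(item, f"numeric but not binary ({value!r})")
    if isinstance(value, str):
        text = value.strip().lower()
        if text in ("", "nan", "na"):
            raise IncompleteRecordError(item)
        if text in ("0", "1"):
            return int(text)
        if text in ("no", "n"):
            # yes/no items: any explicit negative maps to 0
            return 0
        if text in ("y",):
            return 1
        if text in profile.positive_set(item):
            return 1
        # A recognised-but-negative raw response maps to 0; we accept any
        # non-empty string outside the positive set as a negative response
        # so profiles only need to enumerate the positive categories.
        return 0
    raise IncompleteRecordError(item, f"unsupported type {type(value).__name__}")


def map_item_responses(
    raw: Mapping[str, object], profile: MappingProfile = DEFAULT_PROFILE
) -> np.ndarray:
    """Map raw (or pre-dichotomised) responses to the ordered 8-vector.

    Parameters
    ----------
    raw
        Mapping from item name (see :data:`ITEM_NAMES`) to response.  Each
        response may be a 0/1 indicator or raw questionnaire text.
    profile
        Positive-response sets for raw text; defaults to the original-tool
        convention.

    Returns
    -------
    numpy.ndarray of shape (8,), dtype int, ordered per :data:`ITEM_NAMES`.

    Raises
    ------
    IncompleteRecordError
        If any of the eight items is absent or cannot be dichotomised; the
        error names the offending item.
    """
    out = np.empty(N_ITEMS, dtype=np.int64)
    for k, item in enumerate(ITEM_NAMES):
        if item not in raw:
            raise IncompleteRecordError(item, "absent from the record")
        out[k] = _resolve_one(item, raw[item], profile)
    return out


# ---------------------------------------------------------------------------
# Score and outcome classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolScore:
    score: int
    risk_class: RiskClass


@dataclass(frozen=True)
class OutcomeClass:
    band: OutcomeBand
    poor_flag: int

    def __post_init__(self):
        assert self.poor_flag == int(self.band == OutcomeBand.POOR)


def compute_tool_score(indicators: Sequence[int] | np.ndarray) -> ToolScore:
    """Sum the eight binary item indicators and classify risk.

    score = number of positive items (0-8); risk is low iff score <= 3.
    """
    arr = np.asarray(indicators)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected exactly {N_ITEMS} indicators, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("indicators must all be 0 or 1")
    score = int(arr.sum())
    risk = RiskClass.LOW if score <= LOW_RISK_MAX_SCORE else RiskClass.MEDIUM_HIGH
    return ToolScore(score=score, risk_class=risk)


def classify_outcome(pcs6m: float) -> OutcomeClass:
    """Band a 6-month PCS value by tertiles of the 0-100 scale.

    poor iff pcs <= 33; middle iff 33 < pcs <= 66; good iff pcs > 66.
    Fractional values just above 33 fall in the middle band.
    """
    pcs = float(pcs6m)
    if np.isnan(pcs):
        raise ValueError("pcs6m is missing; exclude the record upstream")
    if not 0.0 <= pcs <= 100.0:
        raise ValueError(f"pcs6m must lie in [0, 100], got {pcs}")
    if pcs <= POOR_OUTCOME_PCS_MAX:
        band = OutcomeBand.POOR
    elif pcs <= GOOD_OUTCOME_PCS_MIN:
        band = OutcomeBand.MIDDLE
    else:
        band = OutcomeBand.GOOD
    return OutcomeClass(band=band, poor_flag=int(band == OutcomeBand.POOR))


@dataclass(frozen=True)
class PatientRecord:
    """One participant: identity, setting, pain region, items, outcome."""

    id: str
    service: str
    region: str
    items: np.ndarray  # 8-vector of 0/1 indicators
    pcs6m: float | None  # None when lost to follow-up

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.pcs6m is not None and not 0.0 <= self.pcs6m <= 100.0:
            raise ValueError(f"pcs6m out of [0, 100]: {self.pcs6m}")

    @property
    def tool_score(self) -> ToolScore:
        return compute_tool_score(self.items)

    @property
    def outcome(self) -> OutcomeClass | None:
        if self.pcs6m is None:
            return None
        return classify_outcome(self.pcs6m)
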