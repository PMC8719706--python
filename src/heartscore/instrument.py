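"""Instrument definition, response records, and validation.

The HEART (HEAlthy Relationship Assessment Tool) is a 42-item,
counselor-administered questionnaire characterizing a woman's primary
partner relationship on five subscales:

========  ===============================  =======
code      name                             # items
========  ===============================  =======
TV        Traditional Values               13
PS        Partner Support                  10
PAC       Partner Abuse & Control          9
PR        Partner Resistance to HIV
          Prevention                       5
HPR       HIV Prevention Readiness         5
========  ===============================  =======

Every item is answered on a 6-point Likert scale, strongly disagree
(coded 1) to strongly agree (coded 6).  The instrument is configuration
driven: subscale membership, item polarity, and response bounds live in a
JSON document so alternative item banks can be swapped in.  The shipped
default carries placeholder item identifiers with exemplar texts attached
where available.
"""

from __future__ import annotations

import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SUBSCALE_CODES",
    "VISIT_INDEX",
    "Polarity",
    "RiskDirection",
    "ItemSpec",
    "SubscaleSpec",
    "InstrumentSpec",
    "ResponseRecord",
    "CovariateRecord",
    "ValidationIssue",
    "ValidationReport",
    "default_instrument_path",
    "load_instrument",
    "write_instrument",
    "orient_responses",
    "validate_responses",
]

SUBSCALE_CODES = ("TV", "PS", "PAC", "PR", "HPR")

#: Visit labels mapped onto a linear time index (units: inter-assessment
#: periods).  The month-1 booster was administered only to participants who
#: reported a new partner; it sits at 0.33 and is excluded from growth
#: models by default because the regular assessment grid is
#: baseline / month 3 / month 6.
VISIT_INDEX: Mapping[str, float] = {
    "baseline": 0.0,
    "month1": 0.33,
    "month3": 1.0,
    "month6": 2.0,
}


class Polarity(str, Enum):
    normal = "normal"
    reversed = "reversed"


class RiskDirection(str, Enum):
    low_is_risk = "low_is_risk"
    high_is_risk = "high_is_risk"
    none = "none"


class ItemSpec(BaseModel):
    item_id: str
    subscale_code: str
    polarity: Polarity = Polarity.normal
    text: Optional[str] = None

    @model_validator(mode="after")
    def _check_code(self) -> "ItemSpec":
        if self.subscale_code not in SUBSCALE_CODES:
            raise ValueError(f"unknown subscale code {self.subscale_code!r}")
        return self


class SubscaleSpec(BaseModel):
    code: str
    name: str
    item_ids: list[str]
    risk_direction: RiskDirection = RiskDirection.none
    declared_n_items: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "SubscaleSpec":
        if self.code not in SUBSCALE_CODES:
            raise ValueError(f"unknown subscale code {self.code!r}")
        if not self.item_ids:
            raise ValueError(f"subscale {self.code} defines no items")
        if self.declared_n_items is not None and self.declared_n_items != len(self.item_ids):
            raise ValueError(
                f"subscale {self.code} declares {self.declared_n_items} items "
                f"but lists {len(self.item_ids)}"
            )
        return self

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


class InstrumentSpec(BaseModel):
    name: str = "HEART"
    subscales: list[SubscaleSpec]
    items: list[ItemSpec]
    response_min: int = 1
    response_max: int = 6

    @model_validator(mode="after")
    def _check(self) -> "InstrumentSpec":
        if (self.response_min, self.response_max) != (1, 6):
            raise ValueError("response codes must span 1 (strongly disagree) to 6 (strongly agree)")
        seen: set[str] = set()
        for it in self.items:
            if it.item_id in seen:
                raise ValueError(f"duplicate item id {it.item_id!r}")
            seen.add(it.item_id)
        membership: dict[str, str] = {}
        for sub in self.subscales:
            for iid in sub.item_ids:
                if iid in membership:
                    raise ValueError(
                        f"item {iid!r} appears in both {membership[iid]} and {sub.code}"
                    )
                membership[iid] = sub.code
        item_ids = {it.item_id for it in self.items}
        if set(membership) != item_ids:
            orphans = item_ids - set(membership)
            dangling = set(membership) - item_ids
            raise ValueError(
                f"item/subscale mismatch: items in no subscale {sorted(orphans)}, "
                f"subscale references to undefined items {sorted(dangling)}"
            )
        for it in self.items:
            if membership[it.item_id] != it.subscale_code:
                raise ValueError(
                    f"item {it.item_id!r} declares subscale {it.subscale_code} "
                    f"but is listed under {membership[it.item_id]}"
                )
        return self

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subscale(self, code: str) -> SubscaleSpec:
        for sub in self.subscales:
            if sub.code == code:
                return sub
        raise KeyError(code)

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def n_items(self) -> int:
        return len(self.items)


class ResponseRecord(BaseModel):
    """One participant-visit row of raw (as-recorded) item responses."""

    participant_id: str
    visit: str
    responses: dict[str, Optional[float]]

    @model_validator(mode="after")
    def _check(self) -> "ResponseRecord":
        if self.visit not in VISIT_INDEX:
            raise ValueError(f"unknown visit {self.visit!r}")
        return self

    @property
    def visit_index(self) -> float:
        return VISIT_INDEX[self.visit]

    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.visit)


class CovariateRecord(BaseModel):
    participant_id: str
    visit: str
    any_ipv: Optional[str] = None  # yes / no
    full_disclosure: Optional[str] = None  # yes / no / not_sure
    lives_with_partner: Optional[str] = None  # yes / no
    age_le_25: Optional[str] = None  # yes / no
    new_partner: Optional[str] = None  # yes / no
    modules_received: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "CovariateRecord":
        yn = {"yes", "no", None}
        for field in ("any_ipv", "lives_with_partner", "age_le_25", "new_partner"):
            if getattr(self, field) not in yn:
                raise ValueError(f"{field} must be yes/no, got {getattr(self, field)!r}")
        if self.full_disclosure not in {"yes", "no", "not_sure", None}:
            raise ValueError(f"full_disclosure must be yes/no/not_sure, got {self.full_disclosure!r}")
        if not set(self.modules_received) <= {"A", "B", "C"}:
            raise ValueError(f"modules_received must be a subset of A/B/C, got {self.modules_received}")
        return self


def default_instrument_path() -> Path:
    return Path(str(resources.files("heartscore").joinpath("data/instrument.json")))


def load_instrument(source: Union[str, Path, Mapping, None] = None) -> InstrumentSpec:
    """Load and validate an instrument configuration.

    Parameters
    ----------
    source
        Path to a JSON document, an already-parsed mapping, or ``None``
        for the shipped default HEART configuration.

    The JSON layout nests items inside their subscale for authoring
    convenience::

        {"name": "HEART", "response_min": 1, "response_max": 6,
         "subscales": [{"code": "TV", "name": "...", "risk_direction": "none",
                        "n_items": 13,
                        "items": [{"id": "tv_01", "polarity": "normal",
                                   "text": "..."}, ...]}, ...]}
    """
    if source is None:
        source = default_instrument_path()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)

    subscales: list[SubscaleSpec] = []
    items: list[ItemSpec] = []
    for sub in doc.get("subscales", []):
        item_specs = sub.get("items", [])
        subscales.append(
            SubscaleSpec(
                code=sub["code"],
                name=sub.get("name", sub["code"]),
                item_ids=[i["id"] for i in item_specs],
                risk_direction=sub.get("risk_direction", "none"),
                declared_n_items=sub.get("n_items"),
            )
        )
        for i in item_specs:
            items.append(
                ItemSpec(
                    item_id=i["id"],
                    subscale_code=sub["code"],
                    polarity=i.get("polarity", "normal"),
                    text=i.get("text"),
                )
            )
    return InstrumentSpec(
        name=doc.get("name", "HEART"),
        subscales=subscales,
        items=items,
        response_min=doc.get("response_min", 1),
        response_max=doc.get("response_max", 6),
    )


def write_instrument(instrument: InstrumentSpec, path: Union[str, Path]) -> None:
    """Serialize an InstrumentSpec back to the nested JSON layout."""
    by_code = {it.item_id: it for it in instrument.items}
    doc = {
        "name": instrument.name,
        "response_min": instrument.response_min,
        "response_max": instrument.response_max,
        "subscales": [
            {
                "code": sub.code,
                "name": sub.name,
                "risk_direction": sub.risk_direction.value,
                "n_items": sub.n_items,
                "items": [
                    {
                        "id": iid,
                        "polarity": by_code[iid].polarity.value,
                        **({"text": by_code[iid].text} if by_code[iid].text else {}),
                    }
                    for iid in sub.item_ids
                ],
            }
            for sub in instrument.subscales
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def orient_responses(record: ResponseRecord, instrument: InstrumentSpec) -> ResponseRecord:
    """Map reversed-polarity items x -> 7 - x; leave the rest untouched.

    Missing responses stay missing.  Applying the operation twice returns
    the original record (it is an involution on the reversed items).
    """
    lo, hi = instrument.response_min, instrument.response_max
    flipped: dict[str, Optional[float]] = {}
    for iid, val in record.responses.items():
        if val is None:
            flipped[iid] = None
            continue
        try:
            pol = instrument.item(iid).polarity
        except KeyError:
            flipped[iid] = val
            continue
        flipped[iid] = (lo + hi) - val if pol is Polarity.reversed else val
    return ResponseRecord(
        participant_id=record.participant_id, visit=record.visit, responses=flipped
    )


class ValidationIssue(BaseModel):
    participant_id: str
    visit: str
    field: Optional[str] = None
    problem: str


class ValidationReport(BaseModel):
    issues: list[ValidationIssue]
    n_records: int
    usable_keys: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_responses(
    records: Sequence[ResponseRecord], instrument: InstrumentSpec
) -> ValidationReport:
    """Report out-of-range codes, unknown items, and duplicate keys.

    Validation never raises: the report lists every violation and flags
    the clean records as usable.
    """
    issues: list[ValidationIssue] = []
    known = set(instrument.item_ids)
    lo, hi = instrument.response_min, instrument.response_max
    seen: set[tuple[str, str]] = set()
    usable: list[tuple[str, str]] = []
    for rec in records:
        clean = True
        key = rec.key()
        if key in seen:
            issues.append(
                ValidationIssue(
                    participant_id=rec.participant_id,
                    visit=rec.visit,
                    problem="duplicate key",
                )
            )
            clean = False
        seen.add(key)
        for iid, val in rec.responses.items():
            if iid not in known:
                issues.append(
                    ValidationIssue(
                        participant_id=rec.participant_id,
                        visit=rec.visit,
                        field=iid,
                        problem="unknown item",
                    )
                )
                clean = False
            elif val is not None and not (lo <= val <= hi):
                issues.append(
                    ValidationIssue(
                        participant_id=rec.participant_id,
                        visit=rec.visit,
                        field=iid,
                        problem=f"out of range: {val:g} not in [{lo}, {hi}]",
                    )
                )
                clean = False
        if clean:
            usable.append(key)
    return ValidationReport(issues=issues, n_records=len(records), usable_keys=usable)
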