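"""CSV/JSON readers and writers for responses, covariates, and reports.

Responses travel as wide CSV: one row per participant-visit, columns
``participant_id, visit, <item ids...>``.  Missing responses are blank
cells or the literal ``NA``.  Covariates are a separate CSV keyed by
(participant_id, visit).  All schema errors name the file, row, and
field.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .instrument import CovariateRecord, InstrumentSpec, ResponseRecord

__all__ = [
    "SchemaError",
    "read_responses",
    "write_responses",
    "read_covariates",
    "write_covariates",
    "write_scores",
    "write_report",
]

_MISSING = {"", "NA", "na", "NaN", "nan", "None"}


class SchemaError(ValueError):
    def __init__(self, path, row: Optional[int], field: Optional[str], message: str):
        self.path, self.row, self.field = str(path), row, field
        loc = f"{path}"
        if row is not None:
            loc += f", row {row}"
        if field is not None:
            loc += f", field {field!r}"
        super().__init__(f"{loc}: {message}")


def read_responses(
    path: Union[str, Path], instrument: Optional[InstrumentSpec] = None
) -> list[ResponseRecord]:
    """Read a wide response CSV into ResponseRecords.

    Item columns are taken from the header (everything after
    participant_id and visit); when an instrument is given, unknown
    columns raise a SchemaError up front.
    """
    path = Path(path)
    records: list[ResponseRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("participant_id", "visit"):
            if col not in header:
                raise SchemaError(path, None, col, "required column missing")
        item_cols = [c for c in header if c not in ("participant_id", "visit")]
        if instrument is not None:
            unknown = set(item_cols) - set(instrument.item_ids)
            if unknown:
                raise SchemaError(path, None, sorted(unknown)[0], "not an instrument item")
        for i, row in enumerate(reader, start=2):
            resp: dict[str, Optional[float]] = {}
            for c in item_cols:
                raw = (row.get(c) or "").strip()
                if raw in _MISSING:
                    resp[c] = None
                else:
                    try:
                        resp[c] = float(raw)
                    except ValueError:
                        raise SchemaError(path, i, c, f"not a number: {raw!r}") from None
            try:
                records.append(
                    ResponseRecord(
                        participant_id=row["participant_id"], visit=row["visit"], responses=resp
                    )
                )
            except ValueError as exc:
                raise SchemaError(path, i, "visit", str(exc)) from None
    return records


def write_responses(
    records: Sequence[ResponseRecord],
    path: Union[str, Path],
    item_ids: Optional[Sequence[str]] = None,
) -> None:
    if item_ids is None:
        item_ids = sorted({iid for r in records for iid in r.responses})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "visit", *item_ids])
        for r in records:
            row = [r.participant_id, r.visit]
            for iid in item_ids:
                v = r.responses.get(iid)
                row.append("" if v is None else (f"{int(v)}" if float(v).is_integer() else f"{v}"))
            w.writerow(row)


_COV_FIELDS = (
    "any_ipv",
    "full_disclosure",
    "lives_with_partner",
    "age_le_25",
    "new_partner",
    "modules_received",
)


def read_covariates(path: Union[str, Path]) -> list[CovariateRecord]:
    path = Path(path)
    out: list[CovariateRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("participant_id", "visit"):
            if col not in header:
                raise SchemaError(path, None, col, "required column missing")
        for i, row in enumerate(reader, start=2):
            kwargs = {}
            for f in _COV_FIELDS:
                raw = (row.get(f) or "").strip()
                if f == "modules_received":
                    kwargs[f] = [m for m in raw.split("|") if m] if raw not in _MISSING else []
                else:
                    kwargs[f] = None if raw in _MISSING else raw
            try:
                out.append(
                    CovariateRecord(
                        participant_id=row["participant_id"], visit=row["visit"], **kwargs
                    )
                )
            except ValueError as exc:
                raise SchemaError(path, i, None, str(exc)) from None
    return out


def write_covariates(records: Sequence[CovariateRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "visit", *_COV_FIELDS])
        for r in records:
            w.writerow(
                [
                    r.participant_id,
                    r.visit,
                    r.any_ipv or "",
                    r.full_disclosure or "",
                    r.lives_with_partner or "",
                    r.age_le_25 or "",
                    r.new_partner or "",
                    "|".join(r.modules_received),
                ]
            )


def write_scores(scores: pd.DataFrame, path: Union[str, Path]) -> None:
    scores.to_csv(path, index=False)


def write_report(report: dict, path: Union[str, Path], markdown: bool = False) -> None:
    """Write a triage report as JSON, or its counselor-readable markdown."""
    path = Path(path)
    if markdown:
        path.write_text(report.get("text", ""), encoding="utf-8")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=str)
            fh.write("\n")
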