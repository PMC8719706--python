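"""Subscale scoring with the mean-of-available missing-item rule.

Item responses within each subscale are summed to give the subscale
score, after replacing any missing item response by the mean of the
available responses from the same subscale.  Equivalently, with ``m`` of
``k`` items missing and ``s`` the sum of the available responses, the
score is ``(k / (k - m)) * s``, which may be fractional.

A score is reported only when at least ``min_present_fraction`` of the
subscale's items were answered (default 0.5): mean imputation from fewer
than half the items is too unstable to act on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .instrument import InstrumentSpec, ResponseRecord, SubscaleSpec, orient_responses

__all__ = ["SubscaleScore", "ScoredVisit", "subscale_score", "score_record", "score_cohort"]


@dataclass(frozen=True)
class SubscaleScore:
    subscale_code: str
    score: Optional[float]
    n_items: int
    n_missing: int
    n_imputed: int
    valid: bool


@dataclass(frozen=True)
class ScoredVisit:
    participant_id: str
    visit: str
    scores: dict[str, SubscaleScore]


def subscale_score(
    oriented: dict[str, Optional[float]],
    subscale: SubscaleSpec,
    min_present_fraction: float = 0.5,
) -> SubscaleScore:
    """Score one subscale from an oriented response mapping.

    ``oriented`` maps item id to a response code (or None when missing);
    items absent from the mapping count as missing.
    """
    if not subscale.item_ids:
        raise ValueError(f"subscale {subscale.code} has no items")
    if not (0 < min_present_fraction <= 1):
        raise ValueError("min_present_fraction must be in (0, 1]")
    k = subscale.n_items
    available = [oriented.get(iid) for iid in subscale.item_ids]
    present = [v for v in available if v is not None]
    m = k - len(present)
    if len(present) < min_present_fraction * k or not present:
        return SubscaleScore(subscale.code, None, k, m, 0, False)
    score = (k / (k - m)) * sum(present)
    return SubscaleScore(subscale.code, score, k, m, m, True)


def score_record(
    record: ResponseRecord,
    instrument: InstrumentSpec,
    min_present_fraction: float = 0.5,
    orient: bool = True,
) -> ScoredVisit:
    """Score all five subscales for one participant-visit."""
    rec = orient_responses(record, instrument) if orient else record
    scores = {
        sub.code: subscale_score(rec.responses, sub, min_present_fraction)
        for sub in instrument.subscales
    }
    return ScoredVisit(record.participant_id, record.visit, scores)


def score_cohort(
    records: Sequence[ResponseRecord],
    instrument: InstrumentSpec,
    min_present_fraction: float = 0.5,
    orient: bool = True,
) -> pd.DataFrame:
    """Score a cohort into a wide table ordered by (participant, visit).

    Columns: participant_id, visit, visit_index, one score column per
    subscale code, plus per-subscale ``<code>_n_imputed`` and
    ``<code>_valid`` flags.
    """
    rows = []
    for rec in records:
        sv = score_record(rec, instrument, min_present_fraction, orient=orient)
        row: dict = {
            "participant_id": sv.participant_id,
            "visit": sv.visit,
            "visit_index": rec.visit_index,
        }
        for code, sc in sv.scores.items():
            row[code] = sc.score
            row[f"{code}_n_imputed"] = sc.n_imputed
            row[f"{code}_valid"] = sc.valid
        rows.append(row)
    cols = ["participant_id", "visit", "visit_index"]
    for sub in instrument.subscales:
        cols += [sub.code, f"{sub.code}_n_imputed", f"{sub.code}_valid"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["participant_id", "visit_index"], kind="stable").reset_index(drop=True)
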