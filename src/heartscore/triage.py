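"""Benchmark classification, risk-zone flags, and module triage.

Each subscale score is compared to a reference mean and standard
deviation taken from the formative development survey.  Scores one or
more SDs below the benchmark are "low", one or more SDs above are
"high", everything else "medium" (boundaries inclusive).  A risk flag is
raised when the extreme level lies in the subscale's risk direction:
low Partner Support, or high Partner Abuse & Control / Partner
Resistance.  Any flag triggers a recommendation for the IPV-prevention
counseling module (C); non-full disclosure triggers the disclosure
module (B); the partner-communication module (A) is the default when
nothing else is recommended.  Counselors may override, and overrides are
always recorded in the audit trail, never silently applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from pydantic import BaseModel, model_validator

from .instrument import SUBSCALE_CODES, RiskDirection
from .scoring import ScoredVisit

__all__ = [
    "Benchmark",
    "BenchmarkSet",
    "ClassifiedScore",
    "ModuleRules",
    "Override",
    "TriageRecommendation",
    "default_benchmark_path",
    "load_benchmarks",
    "classify_score",
    "classify_visit",
    "risk_flags",
    "recommend_modules",
    "triage_visit",
    "render_report",
]

DEFAULT_RISK_DIRECTIONS: Mapping[str, RiskDirection] = {
    "TV": RiskDirection.none,
    "PS": RiskDirection.low_is_risk,
    "PAC": RiskDirection.high_is_risk,
    "PR": RiskDirection.high_is_risk,
    "HPR": RiskDirection.none,
}


class Benchmark(BaseModel):
    subscale_code: str
    mean: float
    sd: float

    @model_validator(mode="after")
    def _check(self) -> "Benchmark":
        if self.sd <= 0:
            raise ValueError(f"benchmark sd for {self.subscale_code} must be > 0")
        return self


class BenchmarkSet(BaseModel):
    benchmarks: dict[str, Benchmark]
    provenance: str = ""

    @model_validator(mode="after")
    def _check(self) -> "BenchmarkSet":
        missing = [c for c in SUBSCALE_CODES if c not in self.benchmarks]
        if missing:
            raise ValueError(f"benchmark set missing subscales: {missing}")
        return self

    def __getitem__(self, code: str) -> Benchmark:
        return self.benchmarks[code]


def default_benchmark_path() -> Path:
    return Path(str(resources.files("heartscore").joinpath("data/benchmarks.json")))


def load_benchmarks(source: Union[str, Path, Mapping, None] = None) -> BenchmarkSet:
    """Load a benchmark JSON ({"provenance": ..., "benchmarks": {code: {mean, sd}}})."""
    if source is None:
        source = default_benchmark_path()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:
        doc = dict(source)
    bmks = {
        code: Benchmark(subscale_code=code, mean=v["mean"], sd=v["sd"])
        for code, v in doc.get("benchmarks", {}).items()
    }
    return BenchmarkSet(benchmarks=bmks, provenance=doc.get("provenance", ""))


@dataclass(frozen=True)
class ClassifiedScore:
    subscale_code: str
    score: float
    z: float
    level: str  # low / medium / high
    risk_flag: bool


def classify_score(
    score: Optional[float],
    benchmark: Benchmark,
    risk_direction: RiskDirection = RiskDirection.none,
) -> Optional[ClassifiedScore]:
    """Classify one score against its benchmark; None for invalid scores."""
    if score is None:
        return None
    z = (score - benchmark.mean) / benchmark.sd
    # "one or more SDs" is boundary-inclusive; the 1e-9 guard keeps scores
    # sitting exactly on the threshold (e.g. mean - sd computed in floating
    # point) from landing on the wrong side
    if z <= -1 + 1e-9:
        level = "low"
    elif z >= 1 - 1e-9:
        level = "high"
    else:
        level = "medium"
    flag = (risk_direction is RiskDirection.low_is_risk and level == "low") or (
        risk_direction is RiskDirection.high_is_risk and level == "high"
    )
    return ClassifiedScore(benchmark.subscale_code, score, z, level, flag)


def classify_visit(
    scored: ScoredVisit,
    benchmarks: BenchmarkSet,
    risk_directions: Optional[Mapping[str, RiskDirection]] = None,
) -> dict[str, Optional[ClassifiedScore]]:
    dirs = dict(DEFAULT_RISK_DIRECTIONS)
    if risk_directions:
        dirs.update(risk_directions)
    return {
        code: classify_score(sc.score, benchmarks[code], dirs.get(code, RiskDirection.none))
        for code, sc in scored.scores.items()
    }


def risk_flags(classified: Mapping[str, Optional[ClassifiedScore]]) -> list[str]:
    """Subscales whose level matches their risk direction, in instrument order."""
    return [
        code
        for code in SUBSCALE_CODES
        if code in classified and classified[code] is not None and classified[code].risk_flag
    ]


class ModuleRules(BaseModel):
    """Configurable module rule table.

    The pilot's rule: module C whenever any subscale is flagged; module B
    whenever disclosure is not full; module A as the default when nothing
    else triggers.
    """

    c_on_any_flag: bool = True
    b_on_disclosure: tuple[str, ...] = ("no", "not_sure")
    a_as_default: bool = True
    triage_at_followup: bool = False  # follow-up visits monitor but do not re-triage


@dataclass(frozen=True)
class Override:
    added: frozenset = frozenset()
    removed: frozenset = frozenset()
    note: str = ""


@dataclass(frozen=True)
class TriageRecommendation:
    participant_id: str
    visit: str
    flags: tuple[str, ...]
    recommended_modules: tuple[str, ...]  # rule-based, pre-override
    final_modules: tuple[str, ...]  # after any counselor override
    override: Optional[Override] = None
    suppressed: bool = False  # follow-up visit with triage disabled


def recommend_modules(
    flags: Sequence[str],
    disclosure_status: Optional[str],
    participant_id: str = "",
    visit: str = "baseline",
    override: Optional[Override] = None,
    rules: Optional[ModuleRules] = None,
) -> TriageRecommendation:
    """Apply the module rule table, then any counselor override.

    The rule-based recommendation is retained unchanged; the override is
    applied on top to produce ``final_modules`` and kept in the audit
    trail with its note.
    """
    rules = rules or ModuleRules()
    if disclosure_status not in {"yes", "no", "not_sure", None}:
        raise ValueError(f"unknown disclosure status {disclosure_status!r}")
    base: set[str] = set()
    if rules.c_on_any_flag and flags:
        base.add("C")
    if disclosure_status in rules.b_on_disclosure:
        base.add("B")
    if rules.a_as_default and not base:
        base.add("A")
    final = set(base)
    if override is not None:
        final |= set(override.added)
        final -= set(override.removed)
        if rules.a_as_default and not final:
            final.add("A")
    order = {"A": 0, "B": 1, "C": 2}
    return TriageRecommendation(
        participant_id=participant_id,
        visit=visit,
        flags=tuple(flags),
        recommended_modules=tuple(sorted(base, key=order.get)),
        final_modules=tuple(sorted(final, key=order.get)),
        override=override,
    )


def triage_visit(
    scored: ScoredVisit,
    benchmarks: BenchmarkSet,
    disclosure_status: Optional[str] = None,
    override: Optional[Override] = None,
    rules: Optional[ModuleRules] = None,
    risk_directions: Optional[Mapping[str, RiskDirection]] = None,
) -> tuple[dict[str, Optional[ClassifiedScore]], TriageRecommendation]:
    """Classify a scored visit and produce a module recommendation.

    At follow-up visits classification is always computed (for
    monitoring) but module recommendation is suppressed unless the rule
    table enables follow-up triage.
    """
    rules = rules or ModuleRules()
    classified = classify_visit(scored, benchmarks, risk_directions)
    flags = risk_flags(classified)
    if scored.visit != "baseline" and not rules.triage_at_followup:
        return classified, TriageRecommendation(
            participant_id=scored.participant_id,
            visit=scored.visit,
            flags=tuple(flags),
            recommended_modules=(),
            final_modules=(),
            override=override,
            suppressed=True,
        )
    rec = recommend_modules(
        flags,
        disclosure_status,
        participant_id=scored.participant_id,
        visit=scored.visit,
        override=override,
        rules=rules,
    )
    return classified, rec


def render_report(
    scored: ScoredVisit,
    classified: Mapping[str, Optional[ClassifiedScore]],
    recommendation: TriageRecommendation,
) -> dict:
    """Build the counselor report: structured dict plus markdown text."""
    lines = [
        f"# HEART report — participant {scored.participant_id}, visit {scored.visit}",
        "",
        "| Subscale | Score | z | Level | Risk flag |",
        "|---|---|---|---|---|",
    ]
    sub_rows = {}
    for code in scored.scores:
        cs = classified.get(code)
        sc = scored.scores[code]
        if cs is None:
            sub_rows[code] = {"score": None, "z": None, "level": "not scored", "risk_flag": False}
            lines.append(f"| {code} | not scored | — | — | — |")
        else:
            sub_rows[code] = {
                "score": cs.score,
                "z": cs.z,
                "level": cs.level,
                "risk_flag": cs.risk_flag,
            }
            lines.append(
                f"| {code} | {cs.score:.1f} | {cs.z:+.2f} | {cs.level} |"
                f" {'YES' if cs.risk_flag else ''} |"
            )
        _ = sc
    lines.append("")
    if recommendation.flags:
        lines.append("Risk zone: " + ", ".join(recommendation.flags))
    else:
        lines.append("Risk zone: none")
    if recommendation.suppressed:
        lines.append("Module recommendation suppressed at follow-up (monitoring only).")
    else:
        lines.append(
            "Recommended modules: "
            + (", ".join(recommendation.final_modules) or "none")
        )
    if recommendation.override is not None:
        ov = recommendation.override
        lines.append(
            f"Counselor override: added {sorted(ov.added) or '[]'}, "
            f"removed {sorted(ov.removed) or '[]'} — {ov.note}"
        )
    report = {
        "participant_id": scored.participant_id,
        "visit": scored.visit,
        "subscales": sub_rows,
        "risk_zone": list(recommendation.flags),
        "recommended_modules": list(recommendation.recommended_modules),
        "final_modules": list(recommendation.final_modules),
        "suppressed": recommendation.suppressed,
        "override": (
            None
            if recommendation.override is None
            else {
                "added": sorted(recommendation.override.added),
                "removed": sorted(recommendation.override.removed),
                "note": recommendation.override.note,
            }
        ),
        "text": "\n".join(lines),
    }
    return report
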