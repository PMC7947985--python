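"""End-to-end orchestration: evidence table -> per-nutrient assessments.

Runs the full sequence for every nutrient in an evidence table: compilation
filters, implied burden scoring, weighting qualification, weight scores,
quantitative burden aggregation, initial qualitative rating and certainty
rating. The result keeps every intermediate quantity so reports can show a
complete audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .aggregation import NutrientAssessment, assess_nutrient
from .burden import BurdenCode, NotRateable, ScaleMismatch, implied_burden
from .certainty import RatedPoint, initial_certainty
from .config import ScoringConfig, default_config
from .evidence import (
    EvidencePoint,
    EvidenceTable,
    ExclusionReason,
    Nutrient,
    compile_filter,
)
from .weighting import assign_weights, qualifies_for_weighting, weight_score


@dataclass(frozen=True)
class PointRecord:
    """Everything the pipeline decided about one data point."""

    point: EvidencePoint
    excluded_reason: Optional[ExclusionReason] = None
    burden_code: Optional[BurdenCode] = None
    not_rateable_reason: Optional[str] = None
    qualifies: bool = False
    disqualify_reason: Optional[str] = None
    weights: Optional[tuple[int, int, int, int, int]] = None
    weight_score: Optional[float] = None

    @property
    def retained(self) -> bool:
        return self.excluded_reason is None


@dataclass(frozen=True)
class AssessmentResult:
    table: EvidenceTable
    records: tuple[PointRecord, ...]
    assessments: tuple[NutrientAssessment, ...]

    def assessment_for(self, nutrient: Nutrient) -> NutrientAssessment:
        for a in self.assessments:
            if a.nutrient is nutrient:
                return a
        raise KeyError(nutrient)

    def records_for(self, nutrient: Nutrient) -> list[PointRecord]:
        return [r for r in self.records if r.point.nutrient is nutrient]


def score_point(
    p: EvidencePoint, table: EvidenceTable, config: ScoringConfig
) -> PointRecord:
    """Score one retained point: implied burden, qualification, weights."""
    code: Optional[BurdenCode] = None
    not_rateable: Optional[str] = None
    try:
        code = implied_burden(p, config.thresholds)
    except (NotRateable, ScaleMismatch) as exc:
        not_rateable = str(exc)
    ok, reason = qualifies_for_weighting(p, table.target, config.weights)
    w = ws = None
    if ok:
        mw = assign_weights(p, table.target, config.weights)
        w = mw.as_tuple()
        ws = weight_score(mw, p.id).value
    return PointRecord(
        point=p,
        burden_code=code,
        not_rateable_reason=not_rateable,
        qualifies=ok,
        disqualify_reason=reason,
        weights=w,
        weight_score=ws,
    )


def assess(
    table: EvidenceTable, config: Optional[ScoringConfig] = None
) -> AssessmentResult:
    """Run the full assessment over a validated evidence table."""
    config = config or default_config()
    retained, excluded = compile_filter(table)
    records: list[PointRecord] = []
    excluded_ids = {p.id: reason for p, reason in excluded}
    for p in table.points:
        if p.id in excluded_ids:
            records.append(PointRecord(point=p, excluded_reason=excluded_ids[p.id]))
        else:
            records.append(score_point(p, retained, config))

    nutrients = sorted(
        {r.point.nutrient for r in records if r.retained}, key=lambda n: n.value
    )
    assessments: list[NutrientAssessment] = []
    for nutrient in nutrients:
        nut_records = [
            r for r in records if r.retained and r.point.nutrient is nutrient
        ]
        pairs = [
            (r.point.id, int(r.burden_code), r.weight_score)
            for r in nut_records
            if r.qualifies and r.burden_code is not None and r.weight_score is not None
        ]
        nonqualifying = [
            r.point.id
            for r in nut_records
            if not (r.qualifies and r.burden_code is not None)
        ]
        a = assess_nutrient(nutrient, pairs, nonqualifying)
        rated = [
            RatedPoint(
                point_id=r.point.id,
                code=r.burden_code,
                weight=r.weight_score
                if (r.qualifies and r.burden_code is not None)
                else None,
            )
            for r in nut_records
        ]
        cert = initial_certainty(rated)
        a = a.model_copy(
            update={
                "initial_certainty": cert.label,
                "final_certainty": cert.label,
                "certainty_clause": cert.triggered_clause,
                "disagreement_pairs": tuple(
                    (p.id_a, p.id_b) for p in cert.disagreements.pairs
                ),
            }
        )
        assessments.append(a)
    return AssessmentResult(
        table=table, records=tuple(records), assessments=tuple(assessments)
    )
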