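"""Decision-maker guidance: priority classes and the final report.

A nutrient whose final burden rating is moderate or high *and* whose
certainty of evidence is moderate or high is a high-priority nutrient gap
for policy, programs and research. Moderate/high burden with only low
certainty marks a potential gap to prioritise for new data collection.
Negligible/low burden nutrients are lower priority regardless of certainty
(low certainty there is flagged as a data-quality note, not a class of its
own), and nutrients with no usable evidence propagate as insufficient.

:func:`render_report` produces the human-readable markdown guidance
document (summary table + technical appendix with every data point, its
weights, scores, triggered clauses, exclusions and overrides) together
with a machine-readable JSON twin that agrees with it rating for rating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .aggregation import NutrientAssessment
from .burden import BurdenCode
from .certainty import CertaintyLevel
from .evidence import TargetSpec
from .pipeline import AssessmentResult, PointRecord


class PriorityClass(str, Enum):
    HIGH_PRIORITY_GAP = "high_priority_gap"
    POTENTIAL_GAP_RESEARCH_PRIORITY = "potential_gap_research_priority"
    LOWER_PRIORITY = "lower_priority"
    INSUFFICIENT_EVIDENCE = "insufficient_evidence"


def classify_priority(
    burden: Optional[BurdenCode], certainty: CertaintyLevel
) -> PriorityClass:
    """Map (final burden rating, final certainty rating) to a priority class."""
    if burden is None or certainty is CertaintyLevel.INSUFFICIENT:
        return PriorityClass.INSUFFICIENT_EVIDENCE
    if burden >= BurdenCode.MODERATE:
        if certainty >= CertaintyLevel.MODERATE:
            return PriorityClass.HIGH_PRIORITY_GAP
        return PriorityClass.POTENTIAL_GAP_RESEARCH_PRIORITY
    return PriorityClass.LOWER_PRIORITY


_PRIORITY_TEXT = {
    PriorityClass.HIGH_PRIORITY_GAP: "High-priority nutrient gap",
    PriorityClass.POTENTIAL_GAP_RESEARCH_PRIORITY: (
        "Potential gap - prioritise new data collection"
    ),
    PriorityClass.LOWER_PRIORITY: "Lower priority",
    PriorityClass.INSUFFICIENT_EVIDENCE: "Insufficient evidence",
}


def _certainty_level(label: Optional[str]) -> CertaintyLevel:
    if label is None:
        return CertaintyLevel.INSUFFICIENT
    return CertaintyLevel[label.upper()]


def assessment_priority(a: NutrientAssessment) -> PriorityClass:
    return classify_priority(a.final_rating, _certainty_level(a.final_certainty))


@dataclass(frozen=True)
class Report:
    markdown: str
    data: dict

    def write(self, md_path, json_path) -> None:
        from pathlib import Path

        Path(md_path).write_text(self.markdown)
        Path(json_path).write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _assessment_dict(a: NutrientAssessment) -> dict:
    return {
        "nutrient": a.nutrient.value,
        "quantitative_score": a.quantitative_score,
        "initial_rating": a.initial_rating.label if a.initial_rating else None,
        "final_rating": a.rating_label,
        "initial_certainty": a.initial_certainty,
        "final_certainty": a.final_certainty,
        "certainty_clause": a.certainty_clause,
        "priority": assessment_priority(a).value,
        "qualifying_point_ids": list(a.qualifying_point_ids),
        "nonqualifying_point_ids": list(a.nonqualifying_point_ids),
        "disagreement_pairs": [list(p) for p in a.disagreement_pairs],
        "rating_override": (
            a.rating_override.model_dump() if a.rating_override else None
        ),
        "certainty_override": (
            a.certainty_override.model_dump() if a.certainty_override else None
        ),
    }


def _point_lines(records: Sequence[PointRecord]) -> list[str]:
    lines = []
    for r in records:
        p = r.point
        if not r.retained:
            lines.append(
                f"- `{p.id}` ({p.indicator}, {p.evidence_type.value}): "
                f"**excluded at compilation** — {r.excluded_reason.value}"
            )
            continue
        burden = r.burden_code.label if r.burden_code is not None else (
            f"not rateable ({r.not_rateable_reason})"
        )
        if r.qualifies and r.weight_score is not None:
            e, g, rw, aw, s = r.weights
            wtxt = (
                f"weights E={e}, G={g}, R={rw}, A={aw}, S={s}; "
                f"weight score {r.weight_score:g}"
            )
        else:
            wtxt = f"not weighted — {r.disqualify_reason}"
        lines.append(
            f"- `{p.id}` ({p.indicator}, {p.evidence_type.value}, "
            f"estimate {p.estimate:g}): implied burden {burden}; {wtxt}"
        )
    return lines


def render_report(
    result: AssessmentResult, title: str = "Nutrient gap assessment"
) -> Report:
    """Render the guidance document and its machine-readable twin.

    Raises ``ValueError`` when there is nothing to report.
    """
    assessments = result.assessments
    if not assessments:
        raise ValueError("no assessments to report")
    target = result.table.target

    data = {
        "target": {
            "area_name": target.area_name,
            "area_population": target.area_population,
            "age_min_months": target.age_min_months,
            "age_max_months": target.age_max_months,
            "sex": target.sex.value,
            "assessment_year": target.assessment_year,
        },
        "assessments": [_assessment_dict(a) for a in assessments],
    }

    md: list[str] = [
        f"# {title}",
        "",
        f"Target population: {target.area_name}, ages "
        f"{target.age_min_months}-{target.age_max_months} months "
        f"({target.sex.value}), assessment year {target.assessment_year}.",
        "",
        "## Summary",
        "",
        "| Nutrient | Burden score | Burden rating | Certainty | Priority |",
        "|---|---|---|---|---|",
    ]
    for a in assessments:
        score = "—" if a.quantitative_score is None else f"{a.quantitative_score:.2f}"
        md.append(
            f"| {a.nutrient.value} | {score} | {a.rating_label} | "
            f"{a.final_certainty or 'insufficient'} | "
            f"{_PRIORITY_TEXT[assessment_priority(a)]} |"
        )
    md += [
        "",
        "High-priority nutrient gaps combine a moderate-or-high burden rating "
        "with moderate-or-high certainty of evidence; moderate-or-high burden "
        "with low certainty marks a potential gap needing new data collection.",
        "",
        "## Appendix: detailed rating justifications",
        "",
    ]
    for a in assessments:
        md.append(f"### {a.nutrient.value}")
        md.append("")
        if a.quantitative_score is not None:
            md.append(
                f"Quantitative burden score {a.quantitative_score:.2f} -> initial "
                f"rating {a.initial_rating.label}; final rating {a.rating_label}."
            )
        else:
            md.append("No qualifying data point: insufficient evidence.")
        md.append(
            f"Certainty: {a.final_certainty or 'insufficient'} "
            f"({a.certainty_clause or 'no clause'})."
        )
        if a.rating_override is not None:
            o = a.rating_override
            md.append(
                f"Rating override: {o.original} -> {o.new} by {o.author or 'panel'}: "
                f"{o.justification}"
            )
        if a.certainty_override is not None:
            o = a.certainty_override
            md.append(
                f"Certainty override: {o.original} -> {o.new} by "
                f"{o.author or 'panel'}: {o.justification}"
            )
        if a.disagreement_pairs:
            md.append(
                "Discordant weighted pairs: "
                + ", ".join(f"({x}, {y})" for x, y in a.disagreement_pairs)
            )
        md.append("")
        md.extend(_point_lines(result.records_for(a.nutrient)))
        md.append("")
    return Report(markdown="\n".join(md), data=data)
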