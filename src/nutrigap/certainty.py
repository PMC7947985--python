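"""Certainty-of-evidence rule engine.

The trustworthiness of each nutrient's burden rating is rated insufficient,
low, moderate or high from the weight scores of its data points and the
disagreements between their implied burden codes. A *disagreement* is a
pair of data points for the same nutrient whose implied burden codes
differ; the clauses only consider disagreements among points above a weight
floor:

high:     >= 1 point with W_s > 80, or >= 2 points with W_s > 50, in either
          case with no disagreement among points with W_s > 50;
moderate: >= 1 point with W_s in (50, 80] with no disagreement among points
          with W_s > 25; or >= 2 points with W_s in [25, 50] with no
          disagreement among points with W_s > 25; or >= 3 weighted points,
          one of which has W_s >= 15, all weighted points concordant;
low:      >= 1 data point surviving the compilation filters;
insufficient: no data point at all.

Clauses are evaluated high-first; the clause that fires is recorded.
Points that survive the compilation filters but do not qualify for a
weight score (or are not rateable against the threshold table) count only
toward the low level and are surfaced for expert review. A discordant
unweighted point never blocks the concordance clauses but is reported as a
warning note on the rating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from itertools import combinations
from typing import Optional, Sequence

from .aggregation import OverrideRecord
from .burden import BurdenCode


class CertaintyLevel(IntEnum):
    INSUFFICIENT = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class RatedPoint:
    """A data point as the certainty engine sees it.

    ``weight`` is ``None`` for points that survived the compilation filters
    but have no weight score (did not qualify for weighting, or were not
    rateable so carry no burden code either — then ``code`` is ``None``).
    """

    point_id: str
    code: Optional[BurdenCode]
    weight: Optional[float]


@dataclass(frozen=True)
class DisagreementPair:
    id_a: str
    id_b: str
    code_a: BurdenCode
    code_b: BurdenCode
    weight_a: float
    weight_b: float


@dataclass(frozen=True)
class DisagreementReport:
    weight_floor: float
    pairs: tuple[DisagreementPair, ...]

    def __bool__(self) -> bool:
        return bool(self.pairs)


@dataclass(frozen=True)
class CertaintyRating:
    level: CertaintyLevel
    triggered_clause: Optional[str]
    disagreements: DisagreementReport
    notes: tuple[str, ...] = ()
    override: Optional[OverrideRecord] = None

    @property
    def label(self) -> str:
        return self.level.label


def _weighted(points: Sequence[RatedPoint]) -> list[RatedPoint]:
    return [p for p in points if p.weight is not None and p.code is not None]


def disagreements(
    points: Sequence[RatedPoint], weight_floor: float
) -> DisagreementReport:
    """All unordered pairs with differing burden codes, both above the floor.

    Only points carrying both a burden code and a weight score enter; a
    pair is listed when its codes differ and min(W_i, W_j) > weight_floor.
    """
    eligible = [p for p in _weighted(points) if p.weight > weight_floor]
    pairs = tuple(
        DisagreementPair(a.point_id, b.point_id, a.code, b.code, a.weight, b.weight)
        for a, b in combinations(eligible, 2)
        if a.code != b.code
    )
    return DisagreementReport(weight_floor=weight_floor, pairs=pairs)


def initial_certainty(points: Sequence[RatedPoint]) -> CertaintyRating:
    """Evaluate the certainty clauses, high first, for one nutrient."""
    report = disagreements(points, 0.0)  # all discordant weighted pairs, for audit
    notes: list[str] = []
    weighted = _weighted(points)
    unweighted = [p for p in points if p not in weighted]
    if unweighted and weighted:
        codes = {p.code for p in weighted}
        for p in unweighted:
            if p.code is not None and codes and {p.code} != codes:
                notes.append(
                    f"unweighted point {p.point_id} is discordant with weighted "
                    "points; it does not block concordance clauses but warrants "
                    "expert review"
                )

    if not points:
        return CertaintyRating(
            level=CertaintyLevel.INSUFFICIENT,
            triggered_clause=None,
            disagreements=report,
        )

    no_disagreement_50 = not disagreements(points, 50.0)
    no_disagreement_25 = not disagreements(points, 25.0)

    clause: Optional[str] = None
    level = CertaintyLevel.LOW
    if any(p.weight > 80 for p in weighted) and no_disagreement_50:
        level, clause = CertaintyLevel.HIGH, "high-1: >=1 point W>80, concordant above 50"
    elif sum(p.weight > 50 for p in weighted) >= 2 and no_disagreement_50:
        level, clause = CertaintyLevel.HIGH, "high-2: >=2 points W>50, concordant above 50"
    elif any(50 < p.weight <= 80 for p in weighted) and no_disagreement_25:
        level, clause = (
            CertaintyLevel.MODERATE,
            "moderate-1: >=1 point W in 51-80, concordant above 25",
        )
    elif sum(25 <= p.weight <= 50 for p in weighted) >= 2 and no_disagreement_25:
        level, clause = (
            CertaintyLevel.MODERATE,
            "moderate-2: >=2 points W in 25-50, concordant above 25",
        )
    elif (
        len(weighted) >= 3
        and any(p.weight >= 15 for p in weighted)
        and len({p.code for p in weighted}) == 1
    ):
        level, clause = (
            CertaintyLevel.MODERATE,
            "moderate-3: >=3 weighted points, one W>=15, fully concordant",
        )
    else:
        clause = "low: >=1 data point meeting minimum inclusion criteria"
    return CertaintyRating(
        level=level,
        triggered_clause=clause,
        disagreements=report,
        notes=tuple(notes),
    )


def apply_certainty_override(
    rating: CertaintyRating,
    new_level: CertaintyLevel,
    justification: str,
    author: str = "",
    date: Optional[str] = None,
) -> CertaintyRating:
    """Documented expert override of a certainty rating (original kept)."""
    record = OverrideRecord(
        original=rating.level.label,
        new=new_level.label,
        justification=justification,
        author=author,
        date=date,
    )
    return CertaintyRating(
        level=new_level,
        triggered_clause=rating.triggered_clause,
        disagreements=rating.disagreements,
        notes=rating.notes,
        override=record,
    )
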