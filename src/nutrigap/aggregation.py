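"""Per-nutrient aggregation: quantitative burden scores and ratings.

The quantitative nutrient-gap burden score for a nutrient is the weighted
mean of its qualifying data points' implied burden codes, weighted by their
composite weight scores:

    score = sum(b_i * W_i) / sum(W_i)

The score lies in [0, 3] and is classified into an initial qualitative
rating — negligible [0, 0.5), low [0.5, 1.5), moderate [1.5, 2.5), high
[2.5, 3] — on the *unrounded* value (reports display two decimals). The
printed two-decimal band edges (0.5-1.49, 1.50-2.49) are resolved as
half-open intervals so every real score receives exactly one rating.

Expert panels may override the initial rating; any change must carry a
non-empty documented justification and preserves the original for audit.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, field_validator

from .burden import BurdenCode
from .evidence import Nutrient


class InsufficientEvidence(Exception):
    """No qualifying data point: no quantitative score can be computed."""


#: Upper edges (exclusive) of the negligible, low and moderate rating bands.
RATING_BOUNDS: tuple[float, float, float] = (0.5, 1.5, 2.5)


def quantitative_burden(pairs: Iterable[tuple[int, float]]) -> float:
    """Weight-score-weighted mean of implied burden codes.

    ``pairs`` are (burden code, weight score) for the nutrient's qualifying
    data points. Raises :class:`InsufficientEvidence` on an empty set and
    ``ValueError`` on nonpositive weights.
    """
    pairs = list(pairs)
    if not pairs:
        raise InsufficientEvidence("no qualifying data points")
    if any(w <= 0 for _, w in pairs):
        raise ValueError("weight scores must be positive")
    num = sum(b * w for b, w in pairs)
    den = sum(w for _, w in pairs)
    return num / den


def initial_rating(score: float) -> BurdenCode:
    """Classify a quantitative burden score into a qualitative rating."""
    if not 0 <= score <= 3:
        raise ValueError(f"burden score {score} outside [0, 3]")
    for code, bound in zip(BurdenCode, RATING_BOUNDS):
        if score < bound:
            return code
    return BurdenCode.HIGH


class OverrideRecord(BaseModel):
    """Audit record for an expert change to an initial rating."""

    model_config = ConfigDict(frozen=True)

    original: str
    new: str
    justification: str
    author: str = ""
    date: Optional[str] = None

    @field_validator("justification")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("override justification must be non-empty")
        return v


class NutrientAssessment(BaseModel):
    """Complete per-nutrient assessment state.

    ``quantitative_score`` and ``initial_rating`` are ``None`` when no data
    point qualified (insufficient evidence). ``final_rating`` differs from
    ``initial_rating`` only when an :class:`OverrideRecord` documents why.
    Certainty fields are filled by the certainty rule engine.
    """

    model_config = ConfigDict(frozen=True)

    nutrient: Nutrient
    qualifying_point_ids: tuple[str, ...] = ()
    nonqualifying_point_ids: tuple[str, ...] = ()
    quantitative_score: Optional[float] = None
    initial_rating: Optional[BurdenCode] = None
    final_rating: Optional[BurdenCode] = None
    rating_override: Optional[OverrideRecord] = None
    initial_certainty: Optional[str] = None
    final_certainty: Optional[str] = None
    certainty_override: Optional[OverrideRecord] = None
    certainty_clause: Optional[str] = None
    disagreement_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def rating_label(self) -> str:
        if self.final_rating is None:
            return "insufficient-evidence"
        return self.final_rating.label


def assess_nutrient(
    nutrient: Nutrient,
    pairs: Sequence[tuple[str, int, float]],
    nonqualifying_ids: Sequence[str] = (),
) -> NutrientAssessment:
    """Build the initial assessment from (point id, burden code, W_s) triples."""
    try:
        score = quantitative_burden([(b, w) for _, b, w in pairs])
    except InsufficientEvidence:
        return NutrientAssessment(
            nutrient=nutrient,
            nonqualifying_point_ids=tuple(nonqualifying_ids),
        )
    rating = initial_rating(score)
    return NutrientAssessment(
        nutrient=nutrient,
        qualifying_point_ids=tuple(pid for pid, _, _ in pairs),
        nonqualifying_point_ids=tuple(nonqualifying_ids),
        quantitative_score=score,
        initial_rating=rating,
        final_rating=rating,
    )


def apply_override(
    a: NutrientAssessment,
    new_rating: BurdenCode,
    justification: str,
    author: str = "",
    date: Optional[str] = None,
) -> NutrientAssessment:
    """Return a copy with a documented expert override of the burden rating."""
    record = OverrideRecord(
        original=a.final_rating.label if a.final_rating is not None else "insufficient-evidence",
        new=new_rating.label,
        justification=justification,
        author=author,
        date=date,
    )
    return a.model_copy(update={"final_rating": new_rating, "rating_override": record})
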