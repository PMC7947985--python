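"""Implied nutrient-gap burden scoring from indicator thresholds.

Each data point's estimate (a deficiency prevalence, a prevalence of
inadequate intake, a coverage percentage, or a population median
concentration) is mapped to one of four ordinal burden categories —
negligible (0), low (1), moderate (2) or high (3) — using per-indicator
threshold rows. Rows are direction-aware: for deficiency prevalences a
higher estimate implies a worse gap; for coverage indicators and the
population median urinary iodine concentration a higher value implies a
smaller gap.

Printed threshold ranges such as ``< 3 | 3-9 | 10-19 | >= 20`` leave real
values like 9.5 between integer bands; each row therefore carries an
interval-closure *dialect* that resolves the printed bands into a total,
non-overlapping partition of the estimate's domain (see
:class:`ThresholdDialect`).
"""

from __future__ import annotations

from enum import Enum, IntEnum
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .evidence import EstimateScale, EvidencePoint, Nutrient


class BurdenCode(IntEnum):
    """Ordinal implied burden: negligible (0) to high (3)."""

    NEGLIGIBLE = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "BurdenCode":
        return cls[label.upper()]


class Direction(str, Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    HIGHER_IS_BETTER = "higher_is_better"


class ThresholdDialect(str, Enum):
    """How printed range boundaries close into a partition.

    ``ASCENDING_LEFT_CLOSED``
        Deficiency-style rows printed ``< b1 | b1- | b2- | >= b3`` with
        ascending boundaries; each category is closed on the left, so the
        gap between printed integer bands (9 -> 10) joins the higher
        (worse) category: [0,b1), [b1,b2), [b2,b3), [b3, top].
    ``DESCENDING_LEFT_CLOSED``
        Better-direction rows printed ``>= b1 | b2-b1 | b3-... | < b3``
        (median urinary iodine); categories closed at their lower ends:
        [b1, top], [b2,b1), [b3,b2), [0,b3). The boundary value itself
        (e.g. a median of exactly 150) takes the milder category.
    ``DESCENDING_TOP_OPEN``
        Coverage rows printed ``> b1 | b2-b1 | b3-... | < b3``; the top
        (negligible) category is open at b1, the printed second band is
        closed at both ends: (b1, top], [b2,b1], [b3,b2), [0,b3).
    """

    ASCENDING_LEFT_CLOSED = "ascending_left_closed"
    DESCENDING_LEFT_CLOSED = "descending_left_closed"
    DESCENDING_TOP_OPEN = "descending_top_open"


class NotRateable(Exception):
    """The point cannot be scored against the threshold table.

    Raised for indicators absent from the table or whose age applicability
    window excludes the study population; such points fall to qualitative
    expert consideration instead of numeric scoring.
    """

    def __init__(self, indicator: str, reason: str):
        self.indicator = indicator
        self.reason = reason
        super().__init__(f"{indicator}: {reason}")


class ScaleMismatch(TypeError):
    """The estimate's scale does not match the threshold row's scale."""


class ThresholdRow(BaseModel):
    """Threshold boundaries for one indicator within one age window.

    ``boundaries`` are the three printed cut values in the printed order
    (ascending for worse-direction rows, descending for better-direction
    rows). ``age_min_months``/``age_max_months`` bound the ages the row
    applies to (``None`` = unbounded); ``nutrients`` optionally restricts
    the row to a nutrient group (used by the inadequate-intake rows, whose
    ranges differ by nutrient).
    """

    model_config = ConfigDict(frozen=True)

    indicator: str
    direction: Direction
    scale: EstimateScale
    boundaries: tuple[float, float, float]
    dialect: ThresholdDialect
    age_min_months: Optional[int] = None
    age_max_months: Optional[int] = None
    nutrients: Optional[tuple[Nutrient, ...]] = None
    note: str = ""

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdRow":
        b = self.boundaries
        if self.dialect is ThresholdDialect.ASCENDING_LEFT_CLOSED:
            ok = b[0] < b[1] < b[2]
        else:
            ok = b[0] > b[1] > b[2]
        if not ok:
            raise ValueError(
                f"boundaries {b} not strictly ordered for dialect {self.dialect}"
            )
        if self.direction is Direction.HIGHER_IS_WORSE and self.dialect is not (
            ThresholdDialect.ASCENDING_LEFT_CLOSED
        ):
            raise ValueError("higher_is_worse rows use the ascending dialect")
        return self

    def applies_to_age(self, age_range: Optional[tuple[int, int]]) -> bool:
        """True when the study age range falls inside this row's window."""
        if self.age_min_months is None and self.age_max_months is None:
            return True
        if age_range is None:
            return False
        lo, hi = age_range
        if self.age_min_months is not None and lo < self.age_min_months:
            return False
        if self.age_max_months is not None and hi > self.age_max_months:
            return False
        return True

    def classify(self, value: float) -> BurdenCode:
        """Map an estimate on this row's scale to a burden code."""
        b1, b2, b3 = self.boundaries
        if self.dialect is ThresholdDialect.ASCENDING_LEFT_CLOSED:
            if value < b1:
                return BurdenCode.NEGLIGIBLE
            if value < b2:
                return BurdenCode.LOW
            if value < b3:
                return BurdenCode.MODERATE
            return BurdenCode.HIGH
        if self.dialect is ThresholdDialect.DESCENDING_LEFT_CLOSED:
            if value >= b1:
                return BurdenCode.NEGLIGIBLE
            if value >= b2:
                return BurdenCode.LOW
            if value >= b3:
                return BurdenCode.MODERATE
            return BurdenCode.HIGH
        # DESCENDING_TOP_OPEN
        if value > b1:
            return BurdenCode.NEGLIGIBLE
        if value >= b2:
            return BurdenCode.LOW
        if value >= b3:
            return BurdenCode.MODERATE
        return BurdenCode.HIGH

    def category_interval(
        self, code: BurdenCode, domain: tuple[float, float]
    ) -> tuple[float, float]:
        """Open-ended (lo, hi) span of a category within ``domain``.

        Endpoint membership follows the dialect; used by the synthetic
        generator to draw estimates from a chosen category.
        """
        lo_d, hi_d = domain
        b1, b2, b3 = self.boundaries
        if self.dialect is ThresholdDialect.ASCENDING_LEFT_CLOSED:
            spans = [(lo_d, b1), (b1, b2), (b2, b3), (b3, hi_d)]
        else:
            spans = [(b1, hi_d), (b2, b1), (b3, b2), (lo_d, b3)]
        lo, hi = spans[int(code)]
        if not lo < hi:
            raise ValueError(f"category {code} empty on domain {domain}")
        return lo, hi


class ThresholdTable(BaseModel):
    """All threshold rows, queried by (indicator, age, nutrient)."""

    model_config = ConfigDict(frozen=True)

    rows: tuple[ThresholdRow, ...]

    def lookup(
        self,
        indicator: str,
        age_range: Optional[tuple[int, int]] = None,
        nutrient: Optional[Nutrient] = None,
    ) -> ThresholdRow:
        """Return the unique applicable row or raise :class:`NotRateable`."""
        named = [r for r in self.rows if r.indicator == indicator]
        if not named:
            raise NotRateable(indicator, "indicator not in threshold table")
        matches = []
        for r in named:
            if not r.applies_to_age(age_range):
                continue
            if r.nutrients is not None and (
                nutrient is None or nutrient not in r.nutrients
            ):
                continue
            matches.append(r)
        if not matches:
            raise NotRateable(
                indicator,
                f"no row applicable to age range {age_range} / nutrient {nutrient}",
            )
        if len(matches) > 1:
            raise ValueError(
                f"threshold table ambiguous: {len(matches)} rows match "
                f"({indicator}, {age_range}, {nutrient})"
            )
        return matches[0]

    def indicators(self) -> list[str]:
        return sorted({r.indicator for r in self.rows})


def lookup_thresholds(
    indicator: str,
    age_range: Optional[tuple[int, int]],
    table: ThresholdTable,
    nutrient: Optional[Nutrient] = None,
) -> ThresholdRow:
    """Functional alias for :meth:`ThresholdTable.lookup`."""
    return table.lookup(indicator, age_range, nutrient)


def implied_burden(p: EvidencePoint, table: ThresholdTable) -> BurdenCode:
    """Assign the implied nutrient-gap burden score for one data point.

    The raw estimate is classified without rounding or truncation. Raises
    :class:`NotRateable` when no threshold row applies and
    :class:`ScaleMismatch` when the estimate's scale disagrees with the
    row's (e.g. a prevalence supplied to the median-concentration row).
    """
    row = table.lookup(p.indicator, p.study_age_range, p.nutrient)
    if row.scale is not p.estimate_scale:
        raise ScaleMismatch(
            f"{p.indicator}: estimate on scale {p.estimate_scale.value}, "
            f"threshold row expects {row.scale.value}"
        )
    return row.classify(p.estimate)


def analyst_adjust(
    p: EvidencePoint,
    justification: str,
    new_estimate: Optional[float] = None,
    new_indicator: Optional[str] = None,
) -> EvidencePoint:
    """Analyst hook for footnote-style adjustments (inflammation, assay).

    Returns a copy of the point with the estimate and/or indicator replaced
    and the justification appended to its comments; the justification must
    be non-empty. The arithmetic of any adjustment is the analyst's.
    """
    if not justification or not justification.strip():
        raise ValueError("analyst adjustment requires a non-empty justification")
    update: dict = {}
    if new_estimate is not None:
        update["estimate"] = new_estimate
    if new_indicator is not None:
        update["indicator"] = new_indicator
    note = f"[adjusted: {justification.strip()}]"
    update["comments"] = f"{p.comments} {note}".strip()
    return p.model_copy(update=update)
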