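"""Evidence data model: the compendium of nutrient-specific data points.

A nutrient-gap assessment starts from a summary table in which each row is a
single nutrient-specific data point — a prevalence of deficiency from a
biomarker survey, a prevalence of inadequate intake from a dietary modeling
study, a food-group coverage indicator, and so on — together with the
metadata needed to weight it: evidence type, geographic representation,
recency, age/sex representation and sample size.

This module defines the typed model for that table, reads and writes it as
delimited text (CSV, UTF-8) or xlsx, validates rows, and applies the initial
compilation filters (recency, sample size, geographic representation,
vulnerable populations).
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator


class Nutrient(str, Enum):
    IRON = "iron"
    VITAMIN_A = "vitamin_a"
    IODINE = "iodine"
    ZINC = "zinc"
    FOLATE = "folate"
    VITAMIN_B12 = "vitamin_b12"
    CALCIUM = "calcium"
    VITAMIN_D = "vitamin_d"
    VITAMIN_C = "vitamin_c"
    THIAMINE = "thiamine"
    NIACIN = "niacin"
    VITAMIN_B6 = "vitamin_b6"
    OTHER = "other"


class EvidenceType(str, Enum):
    """The five main evidence types informative of nutrient gaps.

    ``BIOMARKER``    biological, clinical and functional markers
    ``INDIVIDUAL_DIET``  nutrient adequacy of individual diets
    ``HOUSEHOLD_DIET``   nutrient adequacy of household diets
    ``FOOD_SUPPLY``  nutrient adequacy of national food supplies
    ``FOOD_GROUP``   nutrient-informative food-group intake
    """

    BIOMARKER = "biomarker"
    INDIVIDUAL_DIET = "individual_diet"
    HOUSEHOLD_DIET = "household_diet"
    FOOD_SUPPLY = "food_supply"
    FOOD_GROUP = "food_group"
    OTHER = "other"


class EstimateScale(str, Enum):
    PERCENT_PREVALENCE = "percent_prevalence"
    MEDIAN_CONCENTRATION_UG_PER_L = "median_concentration_ug_per_L"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    ALL = "all"


class TargetSpec(BaseModel):
    """The population an assessment is conducted for.

    ``assessment_year`` anchors all recency arithmetic so results do not
    depend on the wall clock. Age ranges are in months of age,
    ``[min_months, max_months]`` inclusive.
    """

    model_config = ConfigDict(frozen=True)

    area_name: str
    area_population: int = Field(gt=0)
    age_min_months: int = Field(ge=0)
    age_max_months: int = Field(gt=0)
    sex: Sex = Sex.ALL
    very_young_children: bool = False
    assessment_year: int

    @model_validator(mode="after")
    def _age_order(self) -> "TargetSpec":
        if self.age_min_months >= self.age_max_months:
            raise ValueError("age_min_months must be < age_max_months")
        return self

    @property
    def age_range(self) -> tuple[int, int]:
        return (self.age_min_months, self.age_max_months)


class EvidencePoint(BaseModel):
    """One nutrient-specific data point and its metadata.

    ``sample_size`` is ``None`` exactly when the point is a national
    food-supply estimate (food balance sheets have no sample size).
    ``age_sex_category`` is the explicit 1-5 age/sex representation code;
    when absent it can be auto-coded from ``study_age_min_months`` /
    ``study_age_max_months`` (advisory only).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    nutrient: Nutrient
    indicator: str
    estimate: float
    estimate_scale: EstimateScale = EstimateScale.PERCENT_PREVALENCE
    evidence_type: EvidenceType
    geographic_fraction: float
    data_collection_end_year: Optional[int] = None
    age_sex_category: Optional[int] = None
    study_age_min_months: Optional[int] = None
    study_age_max_months: Optional[int] = None
    household_level: bool = False
    sample_size: Optional[int] = None
    vulnerable_population: bool = False
    vulnerable_is_target: bool = False
    very_different_age_sex: Optional[bool] = None
    inflammation_adjusted: Optional[bool] = None
    source: str = ""
    comments: str = ""

    @property
    def study_age_range(self) -> Optional[tuple[int, int]]:
        if self.study_age_min_months is None or self.study_age_max_months is None:
            return None
        return (self.study_age_min_months, self.study_age_max_months)


class Violation(BaseModel):
    """One validation finding; data, not an exception."""

    row: Optional[int] = None
    point_id: Optional[str] = None
    field: str
    rule: str
    message: str


def validate_point(p: EvidencePoint) -> list[Violation]:
    """Check the row-level invariants of a data point.

    Returns an empty list iff all invariants hold. Filter concerns (small
    geographic fraction, old data) are *not* validity concerns and are not
    flagged here; they belong to :func:`compile_filter`.
    """
    out: list[Violation] = []

    def bad(field: str, rule: str, message: str) -> None:
        out.append(Violation(point_id=p.id, field=field, rule=rule, message=message))

    if not p.id:
        bad("id", "non-empty", "point id must be non-empty")
    if not math.isfinite(p.estimate) or p.estimate < 0:
        bad("estimate", "nonnegative", f"estimate {p.estimate!r} must be finite and >= 0")
    elif (
        p.estimate_scale is EstimateScale.PERCENT_PREVALENCE and p.estimate > 100
    ):
        bad("estimate", "percent-range", f"prevalence {p.estimate} outside [0, 100]")
    if not (0 < p.geographic_fraction <= 1):
        bad(
            "geographic_fraction",
            "unit-interval",
            f"geographic_fraction {p.geographic_fraction} outside (0, 1]",
        )
    if p.evidence_type is EvidenceType.FOOD_SUPPLY:
        if p.sample_size is not None:
            bad(
                "sample_size",
                "food-supply-marker",
                "food-supply points carry no sample size (leave blank)",
            )
    else:
        if p.sample_size is None:
            bad(
                "sample_size",
                "required",
                "sample size required for non-food-supply evidence",
            )
        elif p.sample_size <= 0:
            bad("sample_size", "positive", f"sample size {p.sample_size} must be > 0")
    if p.age_sex_category is not None and not (1 <= p.age_sex_category <= 5):
        bad(
            "age_sex_category",
            "ordinal-1-5",
            f"age_sex_category {p.age_sex_category} outside 1..5",
        )
    if (p.study_age_min_months is None) != (p.study_age_max_months is None):
        bad(
            "study_age_min_months",
            "pair",
            "study age range must give both min and max months",
        )
    elif p.study_age_range is not None and not (
        0 <= p.study_age_min_months < p.study_age_max_months
    ):
        bad(
            "study_age_min_months",
            "order",
            f"study age range {p.study_age_range} must satisfy 0 <= min < max",
        )
    return out


class EvidenceTable(BaseModel):
    """A validated evidence compendium for one target population."""

    model_config = ConfigDict(frozen=True)

    target: TargetSpec
    points: tuple[EvidencePoint, ...]

    @model_validator(mode="after")
    def _unique_ids(self) -> "EvidenceTable":
        seen: set[str] = set()
        for p in self.points:
            if p.id in seen:
                raise ValueError(f"duplicate point id {p.id!r}")
            seen.add(p.id)
        return self

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.points)


class SchemaError(ValueError):
    """The file does not match the documented column schema."""


class ValidationError(ValueError):
    """One or more rows violate the data-point invariants."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        lines = "; ".join(
            f"row {v.row}: {v.field}: {v.message}" for v in self.violations[:5]
        )
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"{len(self.violations)} invalid row(s): {lines}{more}")


#: Columns of the evidence compendium file, in canonical order.
COLUMNS: tuple[str, ...] = (
    "id",
    "nutrient",
    "indicator",
    "estimate",
    "estimate_scale",
    "evidence_type",
    "geographic_fraction",
    "data_collection_end_year",
    "age_sex_category",
    "study_age_min_months",
    "study_age_max_months",
    "household_level",
    "sample_size",
    "vulnerable_population",
    "vulnerable_is_target",
    "very_different_age_sex",
    "inflammation_adjusted",
    "source",
    "comments",
)

_REQUIRED = {
    "id",
    "nutrient",
    "indicator",
    "estimate",
    "evidence_type",
    "geographic_fraction",
}

_INT_COLS = (
    "data_collection_end_year",
    "age_sex_category",
    "study_age_min_months",
    "study_age_max_months",
    "sample_size",
)
_BOOL_COLS = (
    "household_level",
    "vulnerable_population",
    "vulnerable_is_target",
    "very_different_age_sex",
    "inflammation_adjusted",
)

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(raw: object) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s == "":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {raw!r} as boolean")


def _cell(raw: object) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    return s if s else None


def read_evidence_table(path: str | Path, target: TargetSpec) -> EvidenceTable:
    """Read an evidence compendium from CSV or xlsx and validate every row.

    The header is matched case-insensitively against :data:`COLUMNS`. A
    missing required column raises :class:`SchemaError`; malformed rows are
    collected (with 1-based data row numbers) and raised together as
    :class:`ValidationError` so a validation report can list them all.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, dtype=object)
    else:
        df = pd.read_csv(path, dtype=object, keep_default_na=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")

    points: list[EvidencePoint] = []
    violations: list[Violation] = []
    for i, rec in enumerate(df.to_dict(orient="records"), start=1):
        try:
            p = _point_from_record(rec)
        except (ValueError, TypeError) as exc:
            violations.append(
                Violation(row=i, field="*", rule="parse", message=str(exc))
            )
            continue
        for v in validate_point(p):
            violations.append(v.model_copy(update={"row": i}))
        points.append(p)
    if violations:
        raise ValidationError(violations)
    table = EvidenceTable(target=target, points=tuple(points))
    _warn_possible_duplicates(table.points)
    return table


def _point_from_record(rec: dict) -> EvidencePoint:
    kwargs: dict = {}
    for col in ("id", "indicator", "source", "comments"):
        val = _cell(rec.get(col))
        if val is not None:
            kwargs[col] = val
    nut = _cell(rec.get("nutrient"))
    if nut is not None:
        kwargs["nutrient"] = Nutrient(nut.lower())
    ev = _cell(rec.get("evidence_type"))
    if ev is not None:
        kwargs["evidence_type"] = EvidenceType(ev.lower())
    scale = _cell(rec.get("estimate_scale"))
    if scale is not None:
        kwargs["estimate_scale"] = EstimateScale(scale)
    for col in ("estimate", "geographic_fraction"):
        val = _cell(rec.get(col))
        if val is not None:
            kwargs[col] = float(val)
    for col in _INT_COLS:
        val = _cell(rec.get(col))
        if val is not None:
            kwargs[col] = int(float(val))
    for col in _BOOL_COLS:
        val = _parse_bool(rec.get(col))
        if val is not None:
            kwargs[col] = val
    kwargs.setdefault("id", "")
    kwargs.setdefault("source", "")
    kwargs.setdefault("comments", "")
    return EvidencePoint(**kwargs)


def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    """Write the compendium as UTF-8 CSV; reading it back reproduces every
    field (floats are written with full ``repr`` precision)."""
    rows = []
    for p in table.points:
        d = p.model_dump(mode="json")
        rows.append({c: d.get(c) for c in COLUMNS})
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(path, index=False, float_format=None)


def _warn_possible_duplicates(points: Iterable[EvidencePoint]) -> None:
    seen: dict[tuple, str] = {}
    for p in points:
        # same source + same indicator/evidence type usually means repeated
        # rounds of one survey; distinct sources are legitimately separate rows
        key = (p.nutrient, p.indicator, p.evidence_type, p.source)
        if key in seen:
            warnings.warn(
                f"points {seen[key]!r} and {p.id!r} share nutrient/indicator/"
                "evidence type; if they come from the same survey methodology, "
                "keep only the most recent as a row (older estimates belong in "
                "the comments column)",
                stacklevel=3,
            )
        else:
            seen[key] = p.id
    return None


class ExclusionReason(str, Enum):
    RECENCY = "recency"
    SAMPLE_SIZE = "sample_size"
    GEOGRAPHIC = "geographic_representation"
    VULNERABLE = "vulnerable_population"


def compile_filter(
    table: EvidenceTable,
    max_age_years: int = 20,
    min_sample_size: int = 50,
    min_geographic_fraction: float = 0.10,
) -> tuple[EvidenceTable, list[tuple[EvidencePoint, ExclusionReason]]]:
    """Apply the compilation filters to a validated evidence table.

    A point is excluded when data collection concluded more than
    ``max_age_years`` before the assessment year, when its sample size is
    below ``min_sample_size`` (food-supply points carry none and are never
    excluded on this ground), when it represents less than
    ``min_geographic_fraction`` of the target area's population, or when its
    participants are a highly vulnerable group that is not itself the target
    population. Boundaries follow the strict inequalities: exactly 20 years
    old, n = 50 and a fraction of exactly 0.10 are all retained.

    Returns the retained table and the excluded points, each tagged with the
    (first applicable) reason. Retained and excluded partition the input.
    """
    retained: list[EvidencePoint] = []
    excluded: list[tuple[EvidencePoint, ExclusionReason]] = []
    for p in table.points:
        reason = _exclusion_reason(
            p, table.target, max_age_years, min_sample_size, min_geographic_fraction
        )
        if reason is None:
            retained.append(p)
        else:
            excluded.append((p, reason))
    return EvidenceTable(target=table.target, points=tuple(retained)), excluded


def _exclusion_reason(
    p: EvidencePoint,
    target: TargetSpec,
    max_age_years: int,
    min_sample_size: int,
    min_geographic_fraction: float,
) -> Optional[ExclusionReason]:
    if (
        p.data_collection_end_year is not None
        and target.assessment_year - p.data_collection_end_year > max_age_years
    ):
        return ExclusionReason.RECENCY
    if (
        p.evidence_type is not EvidenceType.FOOD_SUPPLY
        and p.sample_size is not None
        and p.sample_size < min_sample_size
    ):
        return ExclusionReason.SAMPLE_SIZE
    if p.geographic_fraction < min_geographic_fraction:
        return ExclusionReason.GEOGRAPHIC
    if p.vulnerable_population and not p.vulnerable_is_target:
        return ExclusionReason.VULNERABLE
    return None
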