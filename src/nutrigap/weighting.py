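"""Metadata weights and composite weight scores for data points.

Not every data point is equally robust. Each qualifying point receives five
metadata weights — evidence type (E_w), geographic representation (G_w),
recency of data collection (R_w), age/sex representation (A_w) and sample
size (S_w) — and the composite weight score

    W_s = E_w * (G_w + R_w + A_w + S_w)

which multiplies the evidence-type weight into the other four so the more
robust evidence types dominate. Under the default weights the maximum is
100 (a recent, nationally representative biomarker survey of the exact age
and sex group with n > 1000) and the minimum for a sample-based point is 4.
Missing metadata take the lowest weight for their category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from pydantic import BaseModel, ConfigDict

from .evidence import EvidencePoint, EvidenceType, TargetSpec

#: Life-stage bins (months of age) used only to decide whether a study
#: population is "very different" from the target when no explicit flag is
#: given: under-5 childhood, school-age childhood, adolescence, adulthood.
#: An adjacent under-5 group (e.g. 24-59 m vs a 6-23 m target) shares a
#: stage and is excluded-but-similar, not very different.
_LIFE_STAGES: tuple[tuple[int, Optional[int]], ...] = (
    (0, 59),
    (60, 119),
    (120, 215),
    (216, None),
)


class WeightConfig(BaseModel):
    """Weight bands for the five metadata categories (config-driven)."""

    model_config = ConfigDict(frozen=True)

    evidence_type: Mapping[str, int]
    household_diet_young_children: int = 1
    geographic_bands: tuple[tuple[float, int], ...]
    recency_bands: tuple[tuple[int, int], ...]
    sample_bands: tuple[tuple[int, int], ...]
    max_recency_years_for_weighting: int = 10

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "WeightConfig":
        return cls(
            evidence_type=dict(raw["evidence_type"]),
            household_diet_young_children=raw.get("household_diet_young_children", 1),
            geographic_bands=tuple(
                (float(b["min_fraction"]), int(b["weight"]))
                for b in raw["geographic_bands"]
            ),
            recency_bands=tuple(
                (int(b["max_years"]), int(b["weight"])) for b in raw["recency_bands"]
            ),
            sample_bands=tuple(
                (int(b["min_n"]), int(b["weight"])) for b in raw["sample_bands"]
            ),
            max_recency_years_for_weighting=raw.get(
                "max_recency_years_for_weighting", 10
            ),
        )

    def lowest_geographic(self) -> int:
        return min(w for _, w in self.geographic_bands)

    def lowest_recency(self) -> int:
        return min(w for _, w in self.recency_bands)

    def lowest_sample(self) -> int:
        return min(w for _, w in self.sample_bands)


@dataclass(frozen=True)
class MetadataWeights:
    """The five per-category weights for one data point."""

    E_w: int
    G_w: int
    R_w: int
    A_w: int
    S_w: int

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.E_w, self.G_w, self.R_w, self.A_w, self.S_w)


@dataclass(frozen=True)
class WeightScore:
    value: float
    point_id: str = ""


def weight_score(w: MetadataWeights, point_id: str = "") -> WeightScore:
    """Composite weight score W_s = E_w * (G_w + R_w + A_w + S_w)."""
    return WeightScore(value=w.E_w * (w.G_w + w.R_w + w.A_w + w.S_w), point_id=point_id)


def years_since_collection(p: EvidencePoint, target: TargetSpec) -> Optional[int]:
    """Whole years between data-collection end and the assessment year."""
    if p.data_collection_end_year is None:
        return None
    return target.assessment_year - p.data_collection_end_year


def _life_stages(age_range: tuple[int, int]) -> set[int]:
    lo, hi = age_range
    out = set()
    for i, (s_lo, s_hi) in enumerate(_LIFE_STAGES):
        if hi >= s_lo and (s_hi is None or lo <= s_hi):
            out.add(i)
    return out


def _ranges_disjoint(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def is_very_different_age_sex(p: EvidencePoint, target: TargetSpec) -> bool:
    """Whether the study group excludes and is very different from the target.

    The explicit per-row flag always wins. Absent a flag, the default is
    true only when the study and target age ranges are disjoint *and* share
    no life stage (e.g. adult women vs infants); a study of 24-59-month-olds
    against a 6-23-month target is excluded-but-similar, not very different.
    """
    if p.very_different_age_sex is not None:
        return p.very_different_age_sex
    rng = p.study_age_range
    if rng is None:
        return False
    if not _ranges_disjoint(rng, target.age_range):
        return False
    return not (_life_stages(rng) & _life_stages(target.age_range))


def qualifies_for_weighting(
    p: EvidencePoint, target: TargetSpec, config: Optional[WeightConfig] = None
) -> tuple[bool, Optional[str]]:
    """Whether a (filter-surviving) point enters weight-score calculation.

    Excluded: evidence type *other*; data collected more than 10 years
    before the assessment year; and study populations very different from
    the target age and sex group.
    """
    max_years = config.max_recency_years_for_weighting if config else 10
    if p.evidence_type is EvidenceType.OTHER:
        return False, "evidence-type-other"
    elapsed = years_since_collection(p, target)
    if elapsed is not None and elapsed > max_years:
        return False, f"data collection more than {max_years} years ago"
    if is_very_different_age_sex(p, target):
        return False, "age-sex-group-very-different"
    return True, None


def age_sex_autocode(
    study_age_range: Optional[tuple[int, int]],
    household_level: bool,
    target: TargetSpec,
) -> int:
    """Advisory 1-5 age/sex representation code from study vs target ages.

    5: exact age group. 4: a subgroup within the target covering at least
    half of it, or a broader group at least half of which is the target.
    3: some overlap, below half. 2: household or food-balance-sheet level.
    1: disjoint. An explicit ``age_sex_category`` column always overrides
    this autocode.
    """
    if household_level:
        return 2
    if study_age_range is None:
        return 1
    s_lo, s_hi = study_age_range
    t_lo, t_hi = target.age_range
    if (s_lo, s_hi) == (t_lo, t_hi):
        return 5
    s_len = s_hi - s_lo
    t_len = t_hi - t_lo
    study_within_target = s_lo >= t_lo and s_hi <= t_hi
    target_within_study = t_lo >= s_lo and t_hi <= s_hi
    if study_within_target and t_len > 0 and s_len / t_len >= 0.5:
        return 4
    if target_within_study and s_len > 0 and t_len / s_len >= 0.5:
        return 4
    overlap = min(s_hi, t_hi) - max(s_lo, t_lo)
    if overlap >= 0 and not _ranges_disjoint(study_age_range, target.age_range):
        return 3
    return 1


def assign_weights(
    p: EvidencePoint, target: TargetSpec, config: WeightConfig
) -> MetadataWeights:
    """Assign the five metadata weights for a qualifying data point.

    Any missing metadata field takes the lowest weight for its category.
    Household-diet adequacy is downgraded to weight 1 when the target
    population is very young children, penalising the missing age
    representation beyond what the age/sex category can express.
    """
    e_w = config.evidence_type[p.evidence_type.value]
    if (
        p.evidence_type is EvidenceType.HOUSEHOLD_DIET
        and target.very_young_children
    ):
        e_w = config.household_diet_young_children

    g_w = config.lowest_geographic()
    for min_fraction, w in sorted(config.geographic_bands, reverse=True):
        if p.geographic_fraction >= min_fraction:
            g_w = w
            break

    elapsed = years_since_collection(p, target)
    if elapsed is None:
        r_w = config.lowest_recency()
    else:
        r_w = config.lowest_recency()
        for max_years, w in sorted(config.recency_bands):
            if elapsed <= max_years:
                r_w = w
                break

    if p.age_sex_category is not None:
        a_w = p.age_sex_category
    elif p.study_age_range is not None or p.household_level:
        a_w = age_sex_autocode(p.study_age_range, p.household_level, target)
    else:
        a_w = 1

    if p.evidence_type is EvidenceType.FOOD_SUPPLY:
        s_w = 0
    elif p.sample_size is None:
        s_w = config.lowest_sample()
    else:
        s_w = config.lowest_sample()
        for min_n, w in sorted(config.sample_bands, reverse=True):
            if p.sample_size >= min_n:
                s_w = w
                break

    return MetadataWeights(E_w=e_w, G_w=g_w, R_w=r_w, A_w=a_w, S_w=s_w)
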