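"""Score a small hand-built evidence compendium for one country.

Builds a five-point evidence table for iron and vitamin A in children aged
6-23 months, runs the full assessment, and prints the per-nutrient
quantitative burden score, qualitative rating, certainty and priority.
"""

from nutrigap import (
    EvidencePoint,
    EvidenceTable,
    EvidenceType,
    Nutrient,
    Sex,
    TargetSpec,
    assess,
)
from nutrigap.guidance import assessment_priority

target = TargetSpec(
    area_name="Countryland",
    area_population=8_500_000,
    age_min_months=6,
    age_max_months=23,
    sex=Sex.ALL,
    very_young_children=True,
    assessment_year=2024,
)

points = [
    # national micronutrient survey: ferritin deficiency 28% -> high burden
    EvidencePoint(
        id="iron-bio", nutrient=Nutrient.IRON,
        indicator="serum-ferritin-deficiency", estimate=28.0,
        evidence_type=EvidenceType.BIOMARKER, geographic_fraction=1.0,
        data_collection_end_year=2022, age_sex_category=5,
        study_age_min_months=6, study_age_max_months=23, sample_size=2100,
        source="National Micronutrient Survey 2022",
    ),
    # dietary modeling: inadequate iron intake 31% -> high burden
    EvidencePoint(
        id="iron-diet", nutrient=Nutrient.IRON, indicator="inadequate-intake",
        estimate=31.0, evidence_type=EvidenceType.INDIVIDUAL_DIET,
        geographic_fraction=0.62, data_collection_end_year=2019,
        age_sex_category=4, study_age_min_months=6, study_age_max_months=35,
        sample_size=640, source="Dietary intake study 2019",
    ),
    # iron-rich food intake 41% of children -> high implied burden
    EvidencePoint(
        id="iron-fg", nutrient=Nutrient.IRON, indicator="iron-rich-foods-24h",
        estimate=41.0, evidence_type=EvidenceType.FOOD_GROUP,
        geographic_fraction=1.0, data_collection_end_year=2023,
        age_sex_category=5, study_age_min_months=6, study_age_max_months=23,
        sample_size=5200, source="DHS 2023",
    ),
    # retinol deficiency 8% -> low burden
    EvidencePoint(
        id="va-bio", nutrient=Nutrient.VITAMIN_A,
        indicator="serum-retinol-deficiency", estimate=8.0,
        evidence_type=EvidenceType.BIOMARKER, geographic_fraction=1.0,
        data_collection_end_year=2022, age_sex_category=5,
        study_age_min_months=6, study_age_max_months=23, sample_size=2100,
        source="National Micronutrient Survey 2022",
    ),
    # vitamin A-rich food intake 66% -> moderate implied burden
    EvidencePoint(
        id="va-fg", nutrient=Nutrient.VITAMIN_A,
        indicator="vitamin-a-rich-foods-24h", estimate=66.0,
        evidence_type=EvidenceType.FOOD_GROUP, geographic_fraction=1.0,
        data_collection_end_year=2023, age_sex_category=5,
        study_age_min_months=6, study_age_max_months=23, sample_size=5200,
        source="DHS 2023",
    ),
]

result = assess(EvidenceTable(target=target, points=tuple(points)))

for a in result.assessments:
    print(
        f"{a.nutrient.value:10s} score={a.quantitative_score:.2f} "
        f"rating={a.rating_label:10s} certainty={a.final_certainty:8s} "
        f"priority={assessment_priority(a).value}"
    )
print()
print("The score is the weight-score-weighted mean of each point's implied")
print("burden code (0-3); the rating bands are <0.5 / 0.5-1.5 / 1.5-2.5 / >=2.5.")
print("Certainty follows the published weight-score and disagreement clauses.")
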