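import pytest

from nutrigap import (
    EstimateScale,
    EvidencePoint,
    EvidenceType,
    Nutrient,
    Sex,
    TargetSpec,
    default_config,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def target():
    return TargetSpec(
        area_name="Testland",
        area_population=10_000_000,
        age_min_months=6,
        age_max_months=23,
        sex=Sex.ALL,
        very_young_children=True,
        assessment_year=2024,
    )


@pytest.fixture
def make_point():
    """Factory for a valid biomarker point; override any field by keyword."""

    def _make(**kw):
        base = dict(
            id="p1",
            nutrient=Nutrient.IRON,
            indicator="serum-ferritin-deficiency",
            estimate=12.0,
            estimate_scale=EstimateScale.PERCENT_PREVALENCE,
            evidence_type=EvidenceType.BIOMARKER,
            geographic_fraction=1.0,
            data_collection_end_year=2022,
            age_sex_category=5,
            study_age_min_months=6,
            study_age_max_months=23,
            sample_size=800,
        )
        base.update(kw)
        return EvidencePoint(**base)

    return _make
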