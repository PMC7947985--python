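"""Metadata weights and composite weight scores."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrigap import (
    EvidenceType,
    MetadataWeights,
    Nutrient,
    age_sex_autocode,
    assign_weights,
    qualifies_for_weighting,
    weight_score,
)


class TestQualification:
    def test_evidence_type_other_disqualifies(self, make_point, target):
        ok, reason = qualifies_for_weighting(
            make_point(evidence_type=EvidenceType.OTHER, indicator="other"), target
        )
        assert not ok and "other" in reason

    def test_collection_over_ten_years_ago_disqualifies(self, make_point, target):
        ok, reason = qualifies_for_weighting(
            make_point(data_collection_end_year=2012), target
        )
        assert not ok and "10 years" in reason

    def test_exactly_ten_years_still_qualifies(self, make_point, target):
        ok, _ = qualifies_for_weighting(
            make_point(data_collection_end_year=2014), target
        )
        assert ok

    def test_recent_exact_group_biomarker_qualifies(self, make_point, target):
        ok, reason = qualifies_for_weighting(
            make_point(data_collection_end_year=2022), target
        )
        assert ok and reason is None

    def test_explicit_very_different_flag_wins(self, make_point, target):
        ok, reason = qualifies_for_weighting(
            make_point(very_different_age_sex=True), target
        )
        assert not ok and "very-different" in reason

    def test_adult_women_study_disqualified_for_infant_target(self, make_point, target):
        # disjoint ranges in non-overlapping life stages, no explicit flag
        p = make_point(
            study_age_min_months=240, study_age_max_months=588,
            age_sex_category=None, very_different_age_sex=None,
        )
        ok, _ = qualifies_for_weighting(p, target)
        assert not ok

    def test_adjacent_child_group_is_not_very_different(self, make_point, target):
        p = make_point(
            study_age_min_months=24, study_age_max_months=59,
            age_sex_category=None, very_different_age_sex=None,
        )
        ok, _ = qualifies_for_weighting(p, target)
        assert ok


class TestAssignWeights:
    def test_national_recent_exact_biomarker_gets_maxima(self, cfg, make_point, target):
        p = make_point(
            geographic_fraction=1.0, data_collection_end_year=2023,
            age_sex_category=5, sample_size=5000,
        )
        w = assign_weights(p, target, cfg.weights)
        assert w.as_tuple() == (5, 5, 5, 5, 5)
        assert weight_score(w).value == 100

    def test_household_diet_downgraded_for_very_young_children(
        self, cfg, make_point, target
    ):
        p = make_point(
            evidence_type=EvidenceType.HOUSEHOLD_DIET,
            indicator="inadequate-intake",
            household_level=True,
        )
        assert assign_weights(p, target, cfg.weights).E_w == 1
        older = target.model_copy(update={"very_young_children": False})
        assert assign_weights(p, older, cfg.weights).E_w == 2

    @pytest.mark.parametrize(
        "n, expected", [(5000, 5), (1001, 5), (1000, 4), (500, 4), (499, 3),
                        (300, 3), (299, 2), (100, 2), (99, 1), (50, 1)]
    )
    def test_sample_size_bands_with_strict_top(self, cfg, make_point, target, n, expected):
        p = make_point(sample_size=n)
        assert assign_weights(p, target, cfg.weights).S_w == expected

    @pytest.mark.parametrize(
        "f, expected",
        [(1.0, 5), (0.99, 4), (0.75, 4), (0.74, 3), (0.50, 3), (0.49, 2),
         (0.25, 2), (0.24, 1), (0.10, 1)],
    )
    def test_geographic_bands(self, cfg, make_point, target, f, expected):
        p = make_point(geographic_fraction=f)
        assert assign_weights(p, target, cfg.weights).G_w == expected

    @pytest.mark.parametrize(
        "year, expected",
        [(2024, 5), (2022, 5), (2021, 4), (2020, 4), (2019, 3), (2018, 3),
         (2017, 2), (2016, 2), (2015, 1), (2014, 1)],
    )
    def test_recency_bands_whole_years(self, cfg, make_point, target, year, expected):
        p = make_point(data_collection_end_year=year)
        assert assign_weights(p, target, cfg.weights).R_w == expected

    def test_missing_metadata_take_lowest_weight(self, cfg, make_point, target):
        p = make_point(
            data_collection_end_year=None, age_sex_category=None,
            study_age_min_months=None, study_age_max_months=None,
        )
        w = assign_weights(p, target, cfg.weights)
        assert (w.R_w, w.A_w) == (1, 1)

    def test_food_supply_sample_weight_zero(self, cfg, make_point, target):
        p = make_point(
            evidence_type=EvidenceType.FOOD_SUPPLY,
            indicator="inadequate-intake",
            sample_size=None, household_level=True, age_sex_category=2,
        )
        w = assign_weights(p, target, cfg.weights)
        assert w.S_w == 0 and w.E_w == 1


class TestWeightScore:
    @pytest.mark.parametrize(
        "weights, expected",
        [((5, 5, 5, 5, 5), 100), ((1, 1, 1, 1, 1), 4),
         ((3, 4, 5, 4, 3), 48), ((1, 5, 5, 2, 0), 12)],
    )
    def test_product_sum_formula(self, weights, expected):
        assert weight_score(MetadataWeights(*weights)).value == expected

    def test_exhaustive_bounds_over_all_combinations(self):
        # every sample-based combination of printed weights lies in [4, 100]
        values = [
            weight_score(MetadataWeights(e, g, r, a, s)).value
            for e in (1, 2, 3, 5)
            for g in range(1, 6)
            for r in range(1, 6)
            for a in range(1, 6)
            for s in range(1, 6)
        ]
        assert min(values) == 4 and max(values) == 100

    def test_food_supply_bounds_tighter(self, cfg, make_point, target):
        # national food-supply points: E=1, G=5, A=2, S=0, R in 1..5
        values = []
        for year in range(2014, 2025):
            p = make_point(
                evidence_type=EvidenceType.FOOD_SUPPLY,
                indicator="inadequate-intake",
                sample_size=None, household_level=True, age_sex_category=2,
                geographic_fraction=1.0, data_collection_end_year=year,
            )
            w = assign_weights(p, target, cfg.weights)
            values.append(weight_score(w).value)
        assert min(values) == 8 and max(values) == 12

    @given(
        base=st.tuples(
            st.sampled_from([1, 2, 3, 5]), st.integers(1, 5), st.integers(1, 5),
            st.integers(1, 5), st.integers(0, 5),
        ),
        category=st.integers(1, 4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_improving_any_category_never_decreases_score(self, base, category):
        w = MetadataWeights(*base)
        vals = list(base)
        if category == 0:
            return
        if vals[category] >= 5:
            return
        vals[category] += 1
        better = MetadataWeights(*vals)
        assert weight_score(better).value >= weight_score(w).value

    @given(
        f=st.floats(0.10, 1.0), year=st.integers(2014, 2024),
        cat=st.integers(1, 5), n=st.integers(50, 20000),
        etype=st.sampled_from(
            [EvidenceType.BIOMARKER, EvidenceType.INDIVIDUAL_DIET,
             EvidenceType.HOUSEHOLD_DIET, EvidenceType.FOOD_GROUP]
        ),
    )
    @settings(max_examples=300, derandomize=True)
    def test_score_matches_bruteforce_recomputation(self, f, year, cat, n, etype):
        """W_s from the engine equals an independent recomputation from raw
        metadata via the printed band definitions."""
        from nutrigap import (
            EstimateScale,
            EvidencePoint,
            Sex,
            TargetSpec,
            default_config,
        )

        target = TargetSpec(
            area_name="Testland", area_population=10_000_000,
            age_min_months=6, age_max_months=23, sex=Sex.ALL,
            very_young_children=True, assessment_year=2024,
        )
        p = EvidencePoint(
            id="p", nutrient=Nutrient.IRON, indicator="serum-ferritin-deficiency",
            estimate=12.0, estimate_scale=EstimateScale.PERCENT_PREVALENCE,
            geographic_fraction=f, data_collection_end_year=year,
            age_sex_category=cat, sample_size=n, evidence_type=etype,
            study_age_min_months=6, study_age_max_months=23,
        )
        got = weight_score(assign_weights(p, target, default_config().weights)).value

        e = {"biomarker": 5, "individual_diet": 3, "household_diet": 2,
             "food_group": 1}[etype.value]
        if etype is EvidenceType.HOUSEHOLD_DIET and target.very_young_children:
            e = 1
        g = 5 if f == 1.0 else 4 if f >= 0.75 else 3 if f >= 0.50 else \
            2 if f >= 0.25 else 1
        yrs = target.assessment_year - year
        r = 5 if yrs < 3 else 4 if yrs < 5 else 3 if yrs < 7 else \
            2 if yrs < 9 else 1
        s = 5 if n > 1000 else 4 if n >= 500 else 3 if n >= 300 else \
            2 if n >= 100 else 1
        assert got == e * (g + r + cat + s)


class TestAutocode:
    def test_exact_range_codes_five(self, target):
        assert age_sex_autocode((6, 23), False, target) == 5

    def test_broad_study_with_small_target_share_codes_three(self, target):
        # study 6-59 m vs target 6-23 m: target spans 17/53 < half the study
        assert age_sex_autocode((6, 59), False, target) == 3

    def test_broad_study_with_majority_target_share_codes_four(self, target):
        # study 6-35 m: target spans 17/29 >= half
        assert age_sex_autocode((6, 35), False, target) == 4

    def test_subgroup_covering_half_the_target_codes_four(self, target):
        assert age_sex_autocode((6, 17), False, target) == 4  # 11/17 of target

    def test_household_survey_codes_two(self, target):
        assert age_sex_autocode((6, 59), True, target) == 2

    def test_disjoint_ranges_code_one(self, target):
        assert age_sex_autocode((240, 588), False, target) == 1

    def test_explicit_category_wins_over_autocode(self, cfg, make_point, target):
        p = make_point(study_age_min_months=6, study_age_max_months=59,
                       age_sex_category=4)
        assert assign_weights(p, target, cfg.weights).A_w == 4
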