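"""Implied burden scoring: worked examples, totality, monotonicity, config."""

import numpy as np
import pytest

from nutrigap import (
    BurdenCode,
    Direction,
    EstimateScale,
    EvidenceType,
    NotRateable,
    Nutrient,
    ScaleMismatch,
    ThresholdDialect,
    analyst_adjust,
    implied_burden,
    lookup_thresholds,
)


class TestLookup:
    def test_young_child_ferritin_matches_under5_row(self, cfg):
        row = lookup_thresholds("serum-ferritin-deficiency", (6, 23), cfg.thresholds)
        assert row.age_max_months == 59

    def test_median_uic_age_precondition_fails_for_infants(self, cfg):
        with pytest.raises(NotRateable, match="age"):
            lookup_thresholds("median-uic", (6, 23), cfg.thresholds)

    def test_unknown_indicator_not_rateable(self, cfg):
        with pytest.raises(NotRateable, match="not in threshold table"):
            lookup_thresholds("serum-25-oh-d", (6, 23), cfg.thresholds)

    def test_intake_rows_resolved_by_nutrient(self, cfg):
        sentinel = lookup_thresholds(
            "inadequate-intake", (6, 23), cfg.thresholds, Nutrient.IRON
        )
        other = lookup_thresholds(
            "inadequate-intake", (6, 23), cfg.thresholds, Nutrient.CALCIUM
        )
        assert sentinel.boundaries == (5, 15, 25)
        assert other.boundaries == (5, 20, 50)
        with pytest.raises(NotRateable):
            lookup_thresholds("inadequate-intake", (6, 23), cfg.thresholds, None)


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            # serum ferritin deficiency prevalence 12% in under-fives: moderate
            ({}, BurdenCode.MODERATE),
            # median UIC 120 ug/L: low
            (
                dict(
                    nutrient=Nutrient.IODINE,
                    indicator="median-uic",
                    estimate=120.0,
                    estimate_scale=EstimateScale.MEDIAN_CONCENTRATION_UG_PER_L,
                    study_age_min_months=72,
                    study_age_max_months=155,
                ),
                BurdenCode.LOW,
            ),
            # inadequate iron intake 30%: high
            (
                dict(
                    indicator="inadequate-intake",
                    estimate=30.0,
                    evidence_type=EvidenceType.INDIVIDUAL_DIET,
                ),
                BurdenCode.HIGH,
            ),
            # household iodized salt coverage 95%: negligible
            (
                dict(
                    nutrient=Nutrient.IODINE,
                    indicator="household-iodized-salt",
                    estimate=95.0,
                    evidence_type=EvidenceType.FOOD_GROUP,
                    household_level=True,
                ),
                BurdenCode.NEGLIGIBLE,
            ),
            # zero deficiency prevalence: minimal severity
            ({"estimate": 0.0}, BurdenCode.NEGLIGIBLE),
        ],
    )
    def test_printed_category_examples(self, cfg, make_point, kw, expected):
        assert implied_burden(make_point(**kw), cfg.thresholds) is expected

    @pytest.mark.parametrize(
        "estimate, expected",
        [(2.9, 0), (3.0, 1), (9.5, 1), (10.0, 2), (19.999, 2), (20.0, 3), (100.0, 3)],
    )
    def test_deficiency_dialect_boundaries(self, cfg, make_point, estimate, expected):
        # printed "< 3 | 3-9 | 10-19 | >= 20" resolves left-closed
        code = implied_burden(make_point(estimate=estimate), cfg.thresholds)
        assert int(code) == expected

    def test_median_uic_150_resolves_negligible(self, cfg):
        row = lookup_thresholds("median-uic", (72, 155), cfg.thresholds)
        assert row.classify(150.0) is BurdenCode.NEGLIGIBLE
        assert row.classify(149.999) is BurdenCode.LOW
        assert row.classify(99.9) is BurdenCode.MODERATE
        assert row.classify(49.9) is BurdenCode.HIGH

    def test_coverage_90_resolves_low(self, cfg):
        row = lookup_thresholds("household-iodized-salt", None, cfg.thresholds)
        assert row.classify(90.0) is BurdenCode.LOW
        assert row.classify(90.0001) is BurdenCode.NEGLIGIBLE
        assert row.classify(75.0) is BurdenCode.LOW
        assert row.classify(74.9) is BurdenCode.MODERATE
        assert row.classify(59.9) is BurdenCode.HIGH

    def test_scale_mismatch_typed_error(self, cfg, make_point):
        p = make_point(
            nutrient=Nutrient.IODINE,
            indicator="median-uic",
            estimate=40.0,
            study_age_min_months=72,
            study_age_max_months=155,
        )  # prevalence scale supplied to a median row
        with pytest.raises(ScaleMismatch):
            implied_burden(p, cfg.thresholds)


class TestRowProperties:
    def _grid(self, row):
        if row.scale is EstimateScale.PERCENT_PREVALENCE:
            return np.linspace(0.0, 100.0, 4001)
        return np.linspace(0.0, 2.0 * max(row.boundaries), 4001)

    def test_totality_every_estimate_gets_one_category(self, cfg):
        for row in cfg.thresholds.rows:
            for v in self._grid(row):
                assert row.classify(float(v)) in BurdenCode

    def test_monotone_in_declared_direction(self, cfg):
        for row in cfg.thresholds.rows:
            codes = [int(row.classify(float(v))) for v in self._grid(row)]
            diffs = np.diff(codes)
            if row.direction is Direction.HIGHER_IS_WORSE:
                assert (diffs >= 0).all(), row.indicator
            else:
                assert (diffs <= 0).all(), row.indicator

    def test_category_intervals_partition_and_agree_with_classify(self, cfg):
        for row in cfg.thresholds.rows:
            domain = (0.0, 100.0) if row.scale is EstimateScale.PERCENT_PREVALENCE \
                else (0.0, 2.0 * max(row.boundaries))
            spans = [row.category_interval(c, domain) for c in BurdenCode]
            total = sum(hi - lo for lo, hi in spans)
            assert total == pytest.approx(domain[1] - domain[0])
            for code, (lo, hi) in zip(BurdenCode, spans):
                mid = (lo + hi) / 2
                assert row.classify(mid) is code


class TestConfigFidelity:
    """The shipped default reproduces every published threshold range."""

    TRANSCRIPTION = {
        # indicator -> (direction, dialect, boundaries, age window months)
        "serum-ferritin-deficiency": ("higher_is_worse", (3, 10, 20), (None, 59)),
        "serum-retinol-deficiency": ("higher_is_worse", (3, 10, 20), (6, 71)),
        "serum-zinc-deficiency": ("higher_is_worse", (3, 10, 20), (None, 119)),
        "serum-folate-deficiency": ("higher_is_worse", (3, 10, 20), (None, None)),
        "plasma-b12-deficiency": ("higher_is_worse", (3, 10, 20), (None, None)),
        "uic-below-100": ("higher_is_worse", (25, 50, 75), (72, None)),
        "median-uic": ("higher_is_better", (150, 100, 50), (72, None)),
        "total-goiter-rate": ("higher_is_worse", (3, 10, 20), (72, 155)),
        "vitamin-a-rich-foods-24h": ("higher_is_better", (90, 75, 60), (6, 23)),
        "iron-rich-foods-24h": ("higher_is_better", (70, 60, 50), (6, 23)),
        "household-iodized-salt": ("higher_is_better", (90, 75, 60), (None, None)),
        "household-adequately-iodized-salt": ("higher_is_better", (80, 65, 50), (None, None)),
    }
    INTAKE = {
        frozenset({"iron", "vitamin_a", "zinc", "folate", "vitamin_b12"}): (5, 15, 25),
        frozenset({"calcium", "niacin", "thiamine", "vitamin_b6"}): (5, 20, 50),
        frozenset({"vitamin_c"}): (10, 30, 50),
    }

    def test_all_singleton_rows_match_transcription(self, cfg):
        rows = {r.indicator: r for r in cfg.thresholds.rows if r.nutrients is None}
        assert set(rows) == set(self.TRANSCRIPTION)
        for name, (direction, bounds, (lo, hi)) in self.TRANSCRIPTION.items():
            r = rows[name]
            assert r.direction.value == direction, name
            assert r.boundaries == bounds, name
            assert (r.age_min_months, r.age_max_months) == (lo, hi), name

    def test_intake_rows_match_transcription(self, cfg):
        rows = [r for r in cfg.thresholds.rows if r.nutrients is not None]
        got = {
            frozenset(n.value for n in r.nutrients): r.boundaries for r in rows
        }
        assert got == self.INTAKE
        assert all(r.indicator == "inadequate-intake" for r in rows)


def test_analyst_adjustment_requires_justification(cfg, make_point):
    p = make_point(estimate=22.0)
    adj = analyst_adjust(p, "inflammation-adjusted per regression correction",
                         new_estimate=15.0)
    assert adj.estimate == 15.0 and "adjusted" in adj.comments
    assert implied_burden(adj, cfg.thresholds) is BurdenCode.MODERATE
    with pytest.raises(ValueError, match="justification"):
        analyst_adjust(p, "  ")
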