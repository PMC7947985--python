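# Default scoring configuration: indicator thresholds for implied burden
# categories and metadata weights for weight-score calculation.
#
# Threshold boundaries are the three printed cut values per indicator, in
# printed order; `dialect` resolves how boundary values and the gaps between
# printed integer bands close into a total partition (see
# nutrigap.burden.ThresholdDialect). Ages are months; omitted bounds are
# unbounded. All estimates are percent prevalence unless `scale` says
# otherwise.

thresholds:
  - indicator: serum-ferritin-deficiency
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [3, 10, 20]
    dialect: ascending_left_closed
    age_max_months: 59
    note: >-
      Serum ferritin < 12 ug/L, children under 5 y (the deficiency cutoff is
      < 15 ug/L above 5 y). Severity ranges mirror the WHO vitamin A
      deficiency prevalence guidance, applied across sentinel biomarkers.
  - indicator: serum-retinol-deficiency
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [3, 10, 20]
    dialect: ascending_left_closed
    age_min_months: 6
    age_max_months: 71
    note: >-
      Serum retinol < 0.7 umol/L, ages 6-71 months; ranges coincide with WHO
      public-health-significance recommendations for vitamin A deficiency.
  - indicator: serum-zinc-deficiency
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [3, 10, 20]
    dialect: ascending_left_closed
    age_max_months: 119
    note: >-
      Serum zinc < 9.9 umol/L (morning, nonfasting), children under 10 y;
      the afternoon nonfasting cutoff is 8.7 umol/L (a cutoff choice made
      upstream of the estimate, not here).
  - indicator: serum-folate-deficiency
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [3, 10, 20]
    dialect: ascending_left_closed
    note: Serum folate < 10 nmol/L, all ages.
  - indicator: plasma-b12-deficiency
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [3, 10, 20]
    dialect: ascending_left_closed
    note: Plasma vitamin B12 < 150 pmol/L, all ages.
  - indicator: uic-below-100
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [25, 50, 75]
    dialect: ascending_left_closed
    age_min_months: 72
    note: >-
      Prevalence of urinary iodine concentration < 100 ug/L, ages >= 6 y,
      excluding pregnant and lactating women. Ranges chosen to align cutoff
      severity across iodine indicators (not a replacement for WHO guidance
      on public-health severity of iodine deficiency).
  - indicator: median-uic
    direction: higher_is_better
    scale: median_concentration_ug_per_L
    boundaries: [150, 100, 50]
    dialect: descending_left_closed
    age_min_months: 72
    note: >-
      Population median urinary iodine concentration (ug/L), ages >= 6 y,
      excluding pregnant and lactating women; a median of exactly 150
      classifies as negligible.
  - indicator: total-goiter-rate
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [3, 10, 20]
    dialect: ascending_left_closed
    age_min_months: 72
    age_max_months: 155
    note: Total goiter rate, school-age children 6-12 y.
  - indicator: inadequate-intake
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [5, 15, 25]
    dialect: ascending_left_closed
    nutrients: [iron, vitamin_a, zinc, folate, vitamin_b12]
    note: >-
      Prevalence of inadequate intake or availability for the sentinel
      micronutrients with severe deficiency consequences.
  - indicator: inadequate-intake
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [5, 20, 50]
    dialect: ascending_left_closed
    nutrients: [calcium, niacin, thiamine, vitamin_b6]
    note: Prevalence of inadequate intake or availability.
  - indicator: inadequate-intake
    direction: higher_is_worse
    scale: percent_prevalence
    boundaries: [10, 30, 50]
    dialect: ascending_left_closed
    nutrients: [vitamin_c]
    note: Prevalence of inadequate intake or availability, vitamin C.
  - indicator: vitamin-a-rich-foods-24h
    direction: higher_is_better
    scale: percent_prevalence
    boundaries: [90, 75, 60]
    dialect: descending_top_open
    age_min_months: 6
    age_max_months: 23
    note: >-
      Share of children 6-23 months consuming vitamin A-rich foods in the
      past 24 hours.
  - indicator: iron-rich-foods-24h
    direction: higher_is_better
    scale: percent_prevalence
    boundaries: [70, 60, 50]
    dialect: descending_top_open
    age_min_months: 6
    age_max_months: 23
    note: >-
      Share of children 6-23 months consuming iron-rich foods in the past
      24 hours.
  - indicator: household-iodized-salt
    direction: higher_is_better
    scale: percent_prevalence
    boundaries: [90, 75, 60]
    dialect: descending_top_open
    note: Household coverage of iodized salt (any iodization).
  - indicator: household-adequately-iodized-salt
    direction: higher_is_better
    scale: percent_prevalence
    boundaries: [80, 65, 50]
    dialect: descending_top_open
    note: Household coverage of adequately iodized salt (>= 15 ppm).

weights:
  # Evidence-type weight E_w; household-diet adequacy drops to 1 when the
  # target population is very young children.
  evidence_type:
    biomarker: 5
    individual_diet: 3
    household_diet: 2
    food_supply: 1
    food_group: 1
  household_diet_young_children: 1
  # Geographic weight G_w: smallest population fraction (inclusive) per
  # weight; exactly 1.0 (the entire area of interest) scores 5.
  geographic_bands:
    - {min_fraction: 1.00, weight: 5}
    - {min_fraction: 0.75, weight: 4}
    - {min_fraction: 0.50, weight: 3}
    - {min_fraction: 0.25, weight: 2}
    - {min_fraction: 0.10, weight: 1}
  # Recency weight R_w: largest number of whole years elapsed (inclusive)
  # per weight; points more than 10 years old do not qualify for weighting.
  recency_bands:
    - {max_years: 2, weight: 5}
    - {max_years: 4, weight: 4}
    - {max_years: 6, weight: 3}
    - {max_years: 8, weight: 2}
    - {max_years: 10, weight: 1}
  # Sample-size weight S_w: smallest n (inclusive) per weight; "> 1,000" is
  # strict, so n = 1000 scores 4. Food-supply points score 0.
  sample_bands:
    - {min_n: 1001, weight: 5}
    - {min_n: 500, weight: 4}
    - {min_n: 300, weight: 3}
    - {min_n: 100, weight: 2}
    - {min_n: 50, weight: 1}
  max_recency_years_for_weighting: 10
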