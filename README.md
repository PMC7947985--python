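# nutrigap

A rule-based scoring engine for assessing the public health significance of
**population nutrient gaps** from heterogeneous evidence.

Evidence on micronutrient deficiencies and inadequate intake — biomarker
surveys, dietary adequacy modeling, national food-supply accounts,
nutrient-informative food-group indicators — exists for most countries, but
comes in disparate forms of very different robustness and representativeness
and is routinely misread or underused. `nutrigap` implements a transparent,
semiquantitative synthesis of such evidence for analysts and nutrition
program planners: it turns a compendium of nutrient-specific data points
into per-nutrient burden ratings, certainty-of-evidence ratings and
decision-maker priority classes, with a full audit trail.

## The method

Each data point (one row of the compendium) carries a point estimate
(a prevalence % or a population median concentration) plus five metadata
attributes. The engine then computes, per nutrient:

1. **Implied burden score** `b ∈ {0, 1, 2, 3}` (negligible / low / moderate
   / high) from per-indicator threshold ranges — e.g. serum ferritin
   deficiency prevalence `< 3 | 3–9 | 10–19 | ≥ 20` %, median urinary iodine
   `≥ 150 | 100–150 | 50–99 | < 50` µg/L (direction-aware: for coverage
   indicators higher is better).
2. **Weight score** for each qualifying point,
   `W_s = E_w (G_w + R_w + A_w + S_w)`, from the evidence-type, geographic,
   recency, age/sex and sample-size weights (max 100, min 4 for
   sample-based points). Points older than 10 years, of evidence type
   *other*, or from a very different age/sex group are not weighted.
3. **Quantitative burden score** `Σ bᵢ W_sᵢ / Σ W_sᵢ ∈ [0, 3]`, classified
   into a qualitative rating: negligible `[0, 0.5)`, low `[0.5, 1.5)`,
   moderate `[1.5, 2.5)`, high `[2.5, 3]`.
4. **Certainty of evidence** (insufficient / low / moderate / high) from
   rule clauses over weight scores and *disagreements* — pairs of points
   with differing burden codes above a weight floor.
5. **Priority class**: moderate-or-high burden with moderate-or-high
   certainty ⇒ high-priority gap; moderate-or-high burden with low
   certainty ⇒ potential gap, prioritise new data collection.

Expert overrides of burden or certainty ratings are supported and must
carry a documented justification. Agreement between biomarker- and
nonbiomarker-implied ratings is quantified with the **linearly weighted
kappa** `κ_w = (p_o − p_e)/(1 − p_e)` with agreement weights
`w_ij = 1 − |i − j|/3` on the fixed 4-level scale.

A synthetic-data module generates evidence tables with known true burden
categories and controllable ordinal misclassification noise `ε`, so the
whole pipeline is testable end to end without any external data.

## Worked example

`examples/01_score_small_compendium.py` builds a five-point compendium for
iron and vitamin A in children aged 6–23 months and prints:

```
iron       score=3.00 rating=high       certainty=high     priority=high_priority_gap
vitamin_a  score=1.17 rating=low        certainty=high     priority=lower_priority
```

For iron, all three data points (ferritin deficiency 28 %, inadequate
intake 31 %, iron-rich food intake 41 %) imply high burden, so the weighted
mean is 3.00; two concordant weight scores above 50 make certainty high.
For vitamin A the national biomarker survey (retinol deficiency 8 %, low
burden, `W_s = 100`) dominates the moderate-burden food-group indicator
(`W_s = 20`): `(1·100 + 2·20)/120 = 1.17`, rating low.

The other examples show the weight-score arithmetic, the certainty clauses,
biomarker/nonbiomarker agreement via `κ_w`, and ground-truth recovery under
noise. The `nutrigap` CLI (`validate`, `score`, `certainty`, `agree`,
`simulate`, `report`) wraps the same library API for shell use; `report`
writes a markdown guidance document with a technical appendix plus a JSON
twin.

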