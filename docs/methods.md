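# Methods

This note documents the scoring model implemented by `nutrigap`, the
numerical conventions it adopts where the published guidance leaves room,
what the synthetic-data generator does and does not emulate, and known
limitations.

## The scoring model

The engine synthesises nutrient-gap evidence in five stages.

**Compilation filters.** A validated evidence table is filtered before any
scoring: points are dropped when data collection ended more than 20 years
before the assessment year, when the sample size is below 50 (food-supply
points carry no sample size and are exempt), when the study represents less
than 10 % of the target area's population, or when participants are a
highly vulnerable group (e.g. hospitalized patients) that is not itself the
target population. All boundaries follow the strict printed inequalities:
exactly 20 years old, n = 50 and a 10 % fraction are retained. Recency is
always computed against an explicit `assessment_year` on the target
specification, never the wall clock, so results are reproducible. Every
exclusion is recorded with its reason; filtering is a partition and is
idempotent.

**Implied burden.** Each point's estimate maps to an ordinal burden code
0–3 via per-indicator threshold rows (direction-aware, age-windowed, and —
for the inadequate-intake rows — nutrient-group-specific). The shipped
default configuration transcribes the published ranges; a golden-file test
pins every row. Estimates are classified raw, without rounding. Indicators
absent from the table (e.g. vitamin D or calcium biomarkers) raise a
not-rateable signal and fall to qualitative expert consideration; an
analyst adjustment hook can replace an estimate or indicator but requires a
justification string (inflammation adjustment arithmetic is out of scope).

**Interval dialects.** Printed ranges such as `< 3 | 3–9 | 10–19 | ≥ 20`
are not total over the reals (9.5 falls between bands). Three closure
dialects resolve them into exact partitions:

* *ascending, left-closed* (deficiency prevalences): `[0,3) [3,10) [10,20)
  [20,100]` — integer gaps close upward into the worse band;
* *descending, left-closed* (median urinary iodine): `[150,∞) [100,150)
  [50,100) [0,50)` — a median of exactly 150 takes the milder category;
* *descending, top-open* (coverage indicators `> 90 | 75–90 | 60–74 |
  < 60`): `(90,100] [75,90] [60,75) [0,60)` — coverage of exactly 90 is
  low, and the 74→75 gap closes upward into low, matching the printed
  `75–90` band.

Each dialect preserves every printed integer's category membership while
achieving totality and monotonicity (verified by grid sweep).

**Weight scores.** Qualifying points receive five metadata weights —
evidence type E_w ∈ {1, 2, 3, 5} (biomarkers 5; individual-diet adequacy 3;
household-diet adequacy 2, reduced to 1 when the target is very young
children; food supply and food-group intake 1), geographic G_w, recency
R_w, age/sex A_w and sample size S_w — and the composite
`W_s = E_w(G_w + R_w + A_w + S_w)`. Conventions: "< 3 y" means 0–2 whole
elapsed years; a point exactly 10 years old gets R_w = 1 and still
qualifies; `> 1,000` is strict so n = 1000 scores 4; a geographic fraction
of exactly 1.0 ("the entire area") scores 5 and the band edges are closed
below (0.75 → 4); any missing metadata field takes its category's lowest
weight. Sample-based scores span [4, 100]; national food-supply points are
pinned to E_w = 1, A_w = 2, S_w = 0 and (when nationally representative)
G_w = 5, so their scores span only [8, 12] — the printed global minimum of
4 is attainable only by sample-based points.

Points are excluded from weighting (but not from the low-certainty count)
when their evidence type is *other*, data collection was more than 10 years
ago, or the study group is "very different" from the target. The last is an
explicit per-row flag; when absent it defaults to true only if the study
and target age ranges are disjoint *and* share no life stage (bins: 0–59,
60–119, 120–215, ≥ 216 months), so an adjacent 24–59-month toddler group is
excluded-but-similar rather than very different. An advisory age/sex
autocode (5 exact group; 4 subgroup covering ≥ half the target or broader
group at least half of which is the target; 3 partial overlap; 2
household/food-balance level; 1 disjoint) fills A_w when no explicit
category column is given; the explicit column always wins. The published
column text lists "similar to but excludes the group entirely" under both 3
and 1; the autocoder reserves 3 for partial overlap and gives 1 to disjoint
ranges.

**Aggregation and rating.** The quantitative burden score is the
weight-score-weighted mean of burden codes; it is invariant to rescaling
all weights and lies in the convex hull of the component codes. The rating
bands `< 0.5 | 0.5–1.49 | 1.50–2.49 | ≥ 2.5` are resolved as half-open
intervals [0, 0.5), [0.5, 1.5), [1.5, 2.5), [2.5, 3], and classification
uses the unrounded score (reports display two decimals); a score of 1.495,
inside the printed band gap, therefore rates low. Empty qualifying sets
yield an insufficient-evidence signal, never a number.

**Certainty.** Clauses are evaluated high-first over the weighted points
(those with both a burden code and a weight score): high needs one point
with W_s > 80 or two with W_s > 50, concordant above the floor 50;
moderate needs one point in (50, 80] or two in [25, 50] concordant above
25, or at least three weighted points (one with W_s ≥ 15) that are fully
concordant; any surviving point secures low. "No disagreements with any
data point with a weight score > X" is read symmetrically: all points above
the floor share one code. Points that survive the filters but lack a weight
score count only toward low and never block the concordance clauses; a
discordant unweighted point is surfaced as a review note. The printed
moderate band "51–80" is implemented as (50, 80] so non-integer weight
scores remain classifiable.

One consequence of the published clauses worth knowing: adding a data
point that agrees with the *majority* of existing points can still lower
the certainty rating, because it may create a fresh disagreement with a
concordant-but-minority pair of high-weight points that previously anchored
a moderate clause. Monotonicity holds only for additions to fully
concordant sets, and the property test asserts exactly that.

**Agreement.** The linearly weighted kappa is computed from a 4×4
contingency table with agreement weights `w_ij = 1 − |i−j|/3`; the scale
stays fixed at four categories even when some are unobserved so strata are
comparable. Degenerate margins (expected weighted agreement = 1) yield an
explicit undefined signal. For biomarker/nonbiomarker comparisons, each
qualifying nonbiomarker point is paired with the highest-weight-score
biomarker point of the same nutrient and area (configurable); an
independent brute-force formula oracle and scikit-learn's implementation
cross-check the engine in tests to 1e-12.

**Guidance.** Priority classes are a pure function of the final burden and
certainty ratings; the (negligible/low burden, low certainty) corner —
which the published rules leave unnamed — is grouped under lower priority
with a data-quality note. The report renderer emits a markdown summary
table plus appendix and a JSON twin that agree rating for rating.

## Synthetic data generator

The generator emulates the *structure* of a compiled evidence table for a
target of children aged 6–23 months: per nutrient it draws points whose
evidence types follow a mixture (default 0.4 biomarker, 0.2 individual
diet, 0.1 household diet, 0.1 food supply, 0.2 food group — roughly the
availability pattern of national surveys in low- and middle-income
settings), chooses a rateable indicator for each (ferritin, retinol, serum
zinc/folate/B12, median urinary iodine with a school-age study window,
inadequate intake, food-group coverage), and samples the estimate uniformly
from the true category's threshold interval. With probability ε the
estimate is instead drawn from an adjacent category (ordinal noise;
boundary categories shift inward), so the per-point misclassification rate
is exactly ε. Metadata: 60 % of points are nationally representative,
otherwise the fraction is uniform on [0.10, 1); collection ages are uniform
over 0–8 years; sample sizes are drawn from bands typical of DHS-scale
surveys (150–3000). By default the first point per nutrient is a
"flagship" recent national survey of the exact target group (W_s = 100 for
biomarkers), emulating the presence of a high-quality national
micronutrient survey.

What it does *not* emulate: real biomarker or intake distributions (only
category membership), inflammation adjustment, correlated errors between
surveys, temporal trends, or nutrient-specific data availability patterns.
Passing recovery tests therefore demonstrates that the rule engine
propagates category-level information faithfully — not that the thresholds
themselves are epidemiologically valid for any particular population.

Recovery experiments score, over seeded replicates, the fraction of
nutrient-replicates whose final rating equals the truth. With ε = 0 and a
flagship point, recovery is exactly 100 % with high certainty (all codes
equal the truth, so the weighted mean is integral and concordance is
perfect); recovery declines in ε, near chance for a single low-weight point
at ε = 0.5. Test and experiment sizes (200 replicates for the noise-free
check; 80–100 per ε on a 4-point grid; the ~91k-case exhaustive certainty
enumeration; 1000 random kappa tables) were chosen as the smallest sizes at
which the binomial/enumeration margins are decisive.

## Numerical and degenerate-input conventions

* All classification is exact floating-point comparison against configured
  boundaries; no rounding anywhere in the scoring path.
* Kappa's undefined case is detected as expected agreement within 1e-14 of
  1; random-table margins are bounded well away from that.
* Duplicate-looking rows (same nutrient, indicator, evidence type and
  source) trigger a warning, not automatic deduplication — repeated rounds
  of one survey belong in the comments column, and that judgement is the
  analyst's.
* Overrides are immutable audit records; an empty justification is
  rejected. Report JSON is emitted with sorted keys and no timestamps, so
  identical inputs, configuration and seed give byte-identical outputs.

## Limitations

* Threshold ranges are shipped only for the indicators with published
  guidance; other indicators require expert-supplied configuration rows.
* The "very different age/sex group" default is a coarse life-stage
  heuristic; analysts should set the explicit flag where it matters.
* The biomarker/nonbiomarker pairing rule (highest-weight biomarker as
  reference) is one defensible choice among several; published agreement
  statistics depend on the pairing actually used, so κ_w values computed
  here are comparable across runs of this package but not necessarily to
  externally reported figures.
* Expert review (override) steps are supported as recorded decisions only;
  the package does not model the deliberation itself.
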