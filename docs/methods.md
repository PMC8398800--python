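# Methods

## Scoring model

The HEI-2015 is a density-based index: diet quality is assessed per unit
of energy, so any weighted mix of foods — a person-day, an outlet, a whole
population — can be scored on the same 100-point scale. Thirteen
components are scored piecewise-linearly between a zero-score and a
full-score cut-point and summed. The shipped standards file
(`src/outlethei/data/hei2015_standards.csv`) transcribes the HEI-2015
cut-points: adequacy components reach full points at, per 1000 kcal,
≥0.8 cup-eq total fruits, ≥0.4 cup-eq whole fruits, ≥1.1 cup-eq total
vegetables, ≥0.2 cup-eq greens and beans, ≥1.5 oz-eq whole grains,
≥1.3 cup-eq dairy, ≥2.5 oz-eq total protein foods, ≥0.8 oz-eq seafood and
plant proteins, and a fatty-acid ratio (MUFA+PUFA)/SFA ≥2.5 (zero at
≤1.2); moderation components reach full points at ≤1.8 oz-eq refined
grains and ≤1.1 g sodium per 1000 kcal, ≤6.5% of energy from added sugars
and ≤8% from saturated fat (zero at ≥4.3, ≥2.0, ≥26% and ≥16%
respectively). Maxima (six 5-point, seven 10-point components) sum
to 100. The engine treats the file purely as configuration, so tests can
score synthetic standards through the same code path.

Fixed conversion constants: added sugars contribute 16 kcal per
teaspoon-equivalent and fats 9 kcal per gram (the convention of the
standard scoring code for this index); sodium is stored in mg per item
and scored in g per 1000 kcal.

### Population ratio method

A group's density is the ratio of its weighted component total to its
weighted energy total. This "ratio of means" differs from the mean of
per-person ratios whenever energies differ between persons (an algebraic
fact the test suite demonstrates on a two-person example) and is the
recommended, less biased estimator of a population's mean score. The
implementation aggregates with a single weighted sum per component, so it
is exactly invariant to item splitting, to rescaling all weights by a
positive constant, and to rescaling all amounts and energy jointly.

Degenerate inputs: a group with zero weighted energy cannot be scored and
raises, naming the group. A zero saturated-fat total makes the fatty-acid
ratio +∞ (full points) when unsaturated fat is present, and 0 (zero
points) when it is absent — the continuous limit of the clamp.

### Grades

Letter grades map percent-of-maximum to half-open bands: [90, 100] "A",
[80, 90) "B", [70, 80) "C", [60, 70) "D", [0, 60) "F". The published
grading text labels 50–59% an "F" and leaves 0–49% unnamed; "F" here
covers all of [0, 60). Reported tables round to two decimals with
round-half-even; internal arithmetic is full precision.

## Outlet categorization

Item source labels/codes collapse into seven mutually exclusive detailed
categories (store, school, full-service restaurant, quick-service
restaurant, community food program, homegrown, other); the first four are
the analytic outlets, and the remaining three appear only inside the
all-outlets aggregate, mirroring the small observed counts that preclude
outlet-level comparison. The mapping ships as an editable two-column text
file containing both normalized text labels and the numeric
where-obtained codes used by the national survey; codes can drift across
cycles, so the file — not the code — is the point of maintenance. Unknown
sources raise rather than being bucketed silently. Labels not on the
seven lists (e.g. "Child care center") map to `other` by design.

## Survey variance (Fay-adjusted BRR)

Public files mask the design to a stratum id and two PSUs per stratum.
`build_replicates` assigns each (pseudo-)stratum a distinct zero-sum
column of a Sylvester Hadamard matrix — the smallest power-of-two order
strictly greater than the stratum count, since the all-ones column cannot
be used — and each matrix row defines a replicate: the selected PSU's
respondents get weight × (2 − k), the other PSU's × k, with k = 0.3 by
default (k = 0 recovers classic BRR). Balance makes the mean replicate
weight equal the base weight. Strata with more than two PSUs are
collapsed into pseudo-pairs by PSU sort order (an odd trailing PSU joins
the final pair), logged; singleton-PSU strata are an error.

For any statistic θ(data, weights), `SE² = (1/(R(1−k)²)) Σᵣ (θᵣ − θ̂)²`.
For linear statistics this reproduces the textbook two-PSU-per-stratum
stratified estimator exactly; for nonlinear statistics on two strata the
four balanced replicates enumerate every half-sample, giving an exact
brute-force oracle — both equivalences are asserted in the tests.

Pairwise outlet contrasts treat the score difference as a single
statistic per replicate and use a two-sided t test with the
complex-survey degrees of freedom (#PSUs − #strata); p < 0.05 is flagged.
No multiple-testing adjustment is applied to pairwise contrasts (raw
p-values are reported). The cross-cycle trend test regresses the
cycle-level population-ratio score on the cycle index 0..C−1 (centered
OLS slope), recomputes the slope under replicate-r weights in every cycle
(each cycle keeps its own replicate set, built separately), applies the
same BRR formula to the slope, and sums the per-cycle degrees of freedom.
Regressing cycle-level statistics rather than person-level data on time
is a deliberate reading; the alternative would require pooled
person-level replicate weights that masked designs do not support
cleanly.

## Synthetic data generator

The generator emulates the structure the pipeline assumes: item-level
records grouped by respondent; a two-PSU-per-stratum design (round-robin
stratum assignment); lognormal day-1 sampling weights (μ = 9, σ = 0.7,
giving realistically right-skewed weights around 10⁴) and lognormal
per-item energy (μ = 5, σ = 0.6, ≈180 kcal median item); Poisson item
counts with multinomial outlet assignment per age bin; and outlet-specific
true density profiles. Each component amount is
`energy/1000 × true_density × gamma(mean 1, cv)` in its scoring unit,
with percent-of-energy components back-converted through the fixed kcal
factors and the fatty-acid components derived from the saturated-fat
amount. Because the noise is multiplicative, mean-one, and independent of
energy and weights, the population-ratio estimator is consistent for the
configured density, so expected scores are available analytically
(`expected_scores` scores the configured densities directly). The default
item-level noise cv is 0.3 — substantial item-to-item heterogeneity
without making small-sample ratios unstable.

The packaged demo truth inverts the scoring map on component-score
targets chosen to resemble recent published national estimates by outlet
(totals near schools 65, stores 62, full-service 51, quick-service 39);
it is a demonstration configuration, not a reproduction of any real-data
estimate. Item rates (store 8, quick-service 2, full-service 1.2, school
0.8 items per respondent) loosely mirror observed calorie shares.

What the generator does **not** emulate: real food-item co-occurrence,
seasonality, day-to-day within-person correlation, differential
nonresponse, or the correlation structure of real survey weights with
demographics. Passing recovery tests therefore show the estimator and
variance machinery are correct under the stated generative model, not
that real-data estimates would be unbiased.

## Problem sizes and numerical choices

Parameter-recovery checks use 2000 respondents (≈24k items) and assert
each outlet's component scores within 1 point and totals within 2 points
of truth; trend recovery injects 1.5 points/cycle over 8 cycles of 1000
respondents, distributing the increment across components in proportion
to score headroom so the expected total is exactly linear. Contrast
calibration runs 500 null simulations of 480 respondents in 24 strata —
enough strata that the t reference distribution (24 df) is not the
binding approximation — and asserts a 5% nominal rejection rate within
[0.03, 0.07]. Scoring under replicate weights is vectorized
(`make_group_score_fn` precomputes the item-component matrix and
respondent index per outlet), which keeps a full calibration run well
under a minute.

## Known limitations

- Real-survey ingestion expects composite pattern-equivalent quantities
  (whole fruits, legumes folded into vegetables and protein) to be
  pre-summed into single columns named by the component dictionary; the
  package does not itself derive HEI inputs from raw database columns.
- SAS transport files are read via pandas' xport reader; writing XPT is
  not supported (synthetic tables are written as CSV).
- No usual-intake modelling, no second-day recalls, no Taylor
  linearization or jackknife variance, and no HEI-2005/2010 variants.
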