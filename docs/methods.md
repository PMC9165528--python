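# Methods

## Accounting model

The unit of account is annual per-capita reactive-nitrogen release,
kg-N·capita⁻¹·yr⁻¹. For one country-year the food N intake of item *m* is

    intake_m = protein supply_m [g/day] · 365/1000 · protein_to_n_m · (1 − waste_m)

with `protein_to_n` defaulting to the Jones factor 0.16 (1/6.25 g N per g
protein), overridable per item. The production-side footprint multiplies
intake by the item's trade-considered VNF; the consumption side multiplies
by (1 − denitrification ratio). The denitrification ratio defaults to 0,
reflecting the absence of N-removing wastewater treatment in the region, so
the consumption footprint equals intake exactly. Annualization uses 365
days throughout (no leap handling).

Religion specificity enters only through category exclusions: national
balance-sheet supplies are identical for all communities, and an excluded
category contributes zero intake for that community. Hindus exclude meat
and offal, eggs, and fish and seafood; Buddhists additionally exclude milk
and dairy; Muslims, Christians, and the aggregate "Others" community are
unrestricted. By default the excluded protein is **not** redistributed to
permitted categories (`AnalysisConfig.redistribute_excluded = False`);
enabling the flag renormalises each community's permitted intake to the
national protein total. Country totals weight the per-community values by
population shares that must sum to 1; regional values are unweighted
country means, for totals and per-community values alike.

## NUE and VNF

Cultivation NUE pools budgets as a ratio of sums — total harvested crop N
over total inputs (fertilizer, manure, atmospheric deposition, biological
fixation, seed N) — rather than a mean of per-crop ratios; the pooled
quotient is the mass-balance-consistent aggregate and the two statistics
are deliberately distinguished. Quotients above 1 (soil N mining) are
arithmetically allowed but logged as warnings, and are capped at 1 before
entering a VNF chain. The domestic VNF is the reciprocal of the product of
cultivation, processing and consumer-level NUEs, each required to lie in
(0, 1]. The trade-considered VNF is the convex combination

    trade VNF = s · domestic VNF + (1 − s) · regional average domestic VNF

with self-sufficiency ratio `s` clamped to [0, 1] on ingest (net exporters
report ratios above 1; clamping keeps the blend inside the interval spanned
by its parents). Decadal table values are equal-weight means of yearly
VNFs within the bucket — the alternative (VNF of decade-pooled budgets) is
a different statistic and is not used. The 1960s bucket covers 1961–1969
because the balance-sheet series begins in 1961; the 2010s bucket is
truncated at 2013. Published tables are rounded half away from zero to 2
decimals; all internal arithmetic is full precision. Crop-level budgets
map to the ten aggregated food categories through a configurable
crop→category table; animal-product categories carry whole-chain NUE
components directly, since no livestock feed-chain model is attempted.
Missing (country, category, decade) cells in a VNF table build are reported
as gaps, never imputed.

## Diet scenarios

The EAT-Lancet planetary health diet is encoded as fixed category shares
(% of food share): cereals 32, starchy roots 2, oil crops and pulses 18,
vegetables 3, fruits 5, other plant products 27, meat and offal 4, dairy 6,
eggs 1, fish and seafood 2. The alteration rule, per (country, community):

* **Decrease side.** Adjustable categories above their target are pulled
  exactly to the target. Gaps of at most 2 share points are suppressed as
  "no change" (configurable threshold), matching the dash convention of
  the published recommendation table.
* **Dairy protection.** Dairy shares are frozen for Muslim and Hindu
  communities and adjustable for the rest. The published table's milk rows
  decrease only in Christian/Others columns even where the Muslim gap
  exceeds the threshold, so the protected set here is {Muslim, Hindu}
  rather than Hindu alone; it is configurable per community.
* **Increase side.** The freed share is distributed over the healthy plant
  categories (fruits, vegetables, oil crops and pulses, other plant
  products) in proportion to their positive target gaps, rounded to integer
  points by largest remainder. The published increase-side cells do not
  follow a stated rule, so only decrease-side cells are reproduced exactly;
  the increase rule is an explicit approximation.
* **Frozen categories.** Meat, eggs and fish shares are never altered, and
  categories a community excludes stay at zero.

Altered supplies scale each category's items proportionally to hit the new
shares. Total daily protein is anchored at 51 g/day (the adult
recommendation) in the default `rescale` mode; `cap` only reduces
over-consumers and `none` keeps the baseline total. The 2,500 kcal/day
calorie anchor is carried as metadata only — the model operates on protein
mass. A category with zero baseline protein but positive altered share is
introduced by splitting its protein evenly over the category's items; if
the category has no items the alteration is infeasible and raises.

The four scenarios freeze the transformed 2013 inputs through 2050: BAU
(no change), NUE (cultivation NUEs of plant categories ×1.3, capped at 1 —
the 30% figure follows the projected global improvement in food-production
NUE by 2050), EAT_LANCET (altered supplies per community), INTEGRATED
(both). The two transformations act on disjoint inputs, so they compose in
either order; applied transformations are recorded on the scenario inputs
and never applied twice, making the build idempotent.

## Forecaster

A univariate, single-layer LSTM implemented from scratch in numpy: input,
forget and output gates through a logistic squash, tanh candidate,
`c_t = f⊙c_{t−1} + i⊙g`, `h_t = o_t⊙tanh(c_t)`, and a linear head mapping
the final hidden state of a sliding window to the next annual value.
Defaults: window 5, hidden size 8, min-max scaling fitted on the training
span (a zero-variance series scales to zeros and inverts exactly, so
constant series project flat). Training is full-batch backpropagation
through time with an Adam update (learning rate 0.02, 300 epochs); plain
gradient descent is available via `optimizer="gd"` but needs substantially
more epochs to pass the naive-baseline checks, which is why Adam is the
default. Gradients are verified against numerical differentiation in the
test suite. Initialization draws from a seeded generator (the seed is a
required parameter — there is no silent default randomness), so identical
seeds give bit-identical weights and projections. The forget-gate bias
starts at 1, the standard choice that keeps early memory open.

Projection is recursive multi-step: predictions are fed back as inputs
until the horizon (default 2050) and inverse-scaled. The reported RMSE is
the in-sample one-step error on the training span; the historical
train/validation split is deliberately not fixed by the model and callers
may hold out a tail. A deterministic damped-linear-trend forecaster
(`trend_projection`, damping 0.98) is provided for runs that must avoid
stochastic training.

## Synthetic worlds

`WorldSpec` defaults describe a six-country region over 1961–2013 with two
items per category (20 items), five religious communities with plausible
national population mixes, a cereal-dominated diet (~58 g protein/day in
the base year with small positive trends), 10% food waste, and
self-sufficiency ratios drawn once per (country, category) from a
Beta(8, 2) (mostly self-sufficient, occasionally import-dependent).
Cultivation NUE trajectories start between 0.36 and 0.50 and drift slowly
downward, scaled per plant category; animal chains use fixed whole-chain
production NUEs (dairy 0.11, meat 0.30, eggs 0.28, fish 0.80) so that
domestic VNF magnitudes and ordering resemble the published table
(dairy highest, fish lowest). Processing and consumer NUEs default to 0.90
and 0.85 — these are free parameters of the chain, not published values.

Budgets are reverse-engineered from the target NUE: a Dirichlet draw fixes
the input composition, and harvested N is the target ratio times pooled
inputs, so the pipeline's cultivation NUE recovers the trajectory exactly.
Supply noise is multiplicative lognormal with one standard-normal draw per
record taken from a seed-split generator independent of the noise scale;
shrinking `noise_sigma` therefore moves every record monotonically toward
its noiseless value, which is what makes the noise-convergence test
meaningful. A closed-form `GroundTruth` evaluates the accounting formulas
directly from the generating parameters, independently of the pipeline
code. The generator emulates trend + noise only: no price shocks,
demographic change, item churn, reporting revisions, or correlated errors —
passing recovery tests demonstrates the correctness of the accounting, not
the realism of any historical estimate. Absolute synthetic footprint
levels are properties of the generator defaults and are not comparable to
published historical values, which require the full balance-sheet stack.

## Problem sizes and numerics

The test suite exercises four-year worlds (sub-second generation); the
acceptance script runs the full 53-year world, trains the forecaster on the
53-point regional series, and completes in about a second. Tolerances:
footprint identities and oracle equivalences at 1e-12, parameter recovery
at 1e-9 (accumulated float summation across ~20 items × 5 communities),
population-weight sums at 1e-9. Tie-breaks: largest-remainder rounding of
integer share deltas resolves ties by gap remainder order; degenerate
inputs (empty budget collections, zero denominators, empty VNF
collections, horizons not beyond the series) raise typed errors rather
than returning sentinels.

## Known limitations

* Footprints are national-average per-capita values; no sub-national,
  age- or gender-stratified accounting.
* Livestock VNFs are supplied, not derived from feed chains.
* Diet alteration's increase side is an approximation (see above); only
  decrease-side shares land exactly on targets.
* The forecaster is a desk-scale univariate model without exogenous
  covariates, hyper-parameter search or prediction intervals.
* Scenario inputs are frozen at transformed 2013 values; no gradual
  adoption path or shock modelling.
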