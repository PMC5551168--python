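# Methods

This note documents the models and algorithms implemented in `tractrisk`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## 1. Population synthesis

### Objective and search space

The unit of assignment is the **household**: a tract's synthetic population
is a multiset of microdata households (with replacement), and individual-
level constraint tables are evaluated over the members of the selected
households. Assigning whole households is required for the household-level
constraints (tenure, household income, head-of-household age and their
crosses), which are untabulatable from severed individuals; it also
preserves within-household correlation of the demographic attributes.

The fitness is the total absolute error (TAE), the standard objective in
combinatorial spatial microsimulation: the unweighted (configurable
per-table weights, default 1) sum over all constraint-table cells of the
absolute difference between tabulated and target counts. TAE is zero
exactly when every cell matches; weights scale it linearly. Cells are the
full cross product of the declared category spaces, so over-representation
of combinations with zero targets is penalized like any other mismatch.

The household head is defined as the **oldest member** — a deterministic
convention that makes the head-age tabulations reproducible; data sources
differ in how headship is recorded, and nothing downstream depends on the
convention beyond consistency between constraint construction and
tabulation.

### Annealing schedule

* Initial selection: households drawn uniformly with replacement until the
  materialized person count first reaches the tract's person target, which
  is the sum of the sex table (every person appears in it).
* Proposal: replace one uniformly chosen selected household with one
  uniformly chosen pool household. Note the proposal preserves the number
  of selected households, so the initial draw fixes the household
  cardinality.
* Acceptance: Metropolis — always for ΔTAE ≤ 0 (ties count as improving, to
  allow plateau drift), probability `exp(−Δ/T)` otherwise.
* Temperature: `T0` auto-calibrated from 200 probe moves so the typical
  worsening move is initially accepted with probability ≈ 0.8
  (`T0 = −mean(Δ⁺)/ln 0.8`; `T0 = 1` if no probe move worsens), then
  geometric cooling `T ← 0.99·T` every 100 proposals.
* Stopping: exact fit (TAE = 0), a proposal budget (default 50,000), or a
  stall limit (default 2,000) counting proposals since the last strict
  improvement of the *current* state. Plateau moves are neutral to the
  stall clock — they are the exploration mechanism, not a failure to
  progress — and only rejected or accepted-worsening proposals count
  against it. Counting "no new best-so-far" instead would terminate runs
  during the hot phase, where the best rarely improves by design.
* Restarts: optionally (`n_restarts`, default 1) the whole schedule is run
  from independent derived substreams and the best restart kept. Single-
  swap moves have deep local minima within a few TAE units of an exact fit
  (escaping them can require a coordinated pair of swaps through worse
  states, which a cold chain cannot accept); independent restarts are the
  standard remedy when an exact or near-exact fit is required.

The best-so-far assignment ever visited is returned, so reported TAE is
non-increasing in the proposal count. Each tract is optimized independently
with a seed derived from (master seed, "anneal", tract id), making results
independent of tract ordering and safe to parallelize.

### Diagnostics

Per tract: initial/final/best TAE, relative TAE (TAE divided by the summed
targets), acceptance rate, proposal count, temperatures, stop reason, and a
best-TAE trace sampled every 100 proposals. A run report aggregates the
mean relative TAE across tracts.

## 2. Outcome regression

Four outcomes are modeled in the fixed chain order **exercise →
fruit/vegetable consumption → BMI → diabetes**; each stage's candidate
predictors are the demographics (sex, age band, race/ethnicity, collapsed
income, education, smoking status, any-alcohol indicator) plus the
*observed* values of earlier-stage outcomes. BMI is a linear model; the
others are logistic (maximum likelihood via IRLS, log-likelihood tolerance
1e-8, at most 100 iterations; Wald standard errors from the observed
information). Degenerate responses and (quasi-)separation raise diagnostic
errors rather than returning unstable coefficients.

**Backward selection** removes whole blocks: the full set of non-reference
indicators of a categorical variable is tested jointly (Wald chi-square,
df = number of non-reference categories; 1-df for binary/continuous terms)
and the block with the largest p-value is dropped while it exceeds
α = 0.05, refitting after each removal. Ties are broken by earliest block
order; the removal history is recorded on the fitted model. Block-wise
removal mirrors how published model tables mark entire variables as
non-significant; within-block category pruning is deliberately not
performed. The Wald test was chosen over the likelihood ratio because it
needs no extra refit per candidate and the selection rule is specified only
through "a p-value".

Fitting is unweighted by default; a per-record survey-weight column is
supported (`freq_weights`/WLS) since telephone health surveys are weighted
designs. Missing data are handled complete-case per model, with the dropped
count logged.

Income is collapsed to three bands (<$25k, $25–35k, ≥$35k) for modeling,
from the finer bands carried on the data — sparse upper categories are the
usual reason published models collapse income.

### Published coefficient table

A packaged JSON transcribes a published four-model coefficient table
(main-effect coefficients, significance markers, blocks dropped as NS,
blocks excluded as N/A by the chain order, reference groups). Ingestion
produces `FittedModel`s with intercept 0 flagged **uncalibrated**; the
prediction layer refuses to run an uncalibrated logistic model. The
published BMI coefficients are on an unstated scale (they are far too small
for raw kg/m²); the pipeline treats that scale as opaque — the linear
intercept can be calibrated to a user-supplied target mean on the model's
own scale, and BMI categorization applies to the calibrated values. Raw
kg/m² should not be assumed when interpreting fixture-based BMI output.

### Intercept calibration

For a logistic model, the intercept solving
`mean expit(c + offsetᵢ) = target` is unique by strict monotonicity and is
found by bracketed root finding on [−60, 60] to 1e-6 on the mean. Chain
calibration proceeds stage by stage, integrating drawn upstream states out
by the law of total probability (enumerating the four
exercise × fruit/veg combinations), so it is deterministic. Default
calibration targets in fixture mode are the packaged citywide prevalences
(0.649 / 0.179 / 0.111).

## 3. Prediction and Monte Carlo

Predictions are restricted to synthetic residents aged **21 and over**
(inclusive; configurable): the population inherits predicted smoking and
alcohol fields that only make sense for adults of legal drinking age. Per
individual, the chain computes each logistic probability given demographics
and drawn upstream outcomes, draws the binary outcome, predicts BMI
deterministically (its residual is *not* redrawn — BMI uncertainty is not
propagated), categorizes it (<18.5 / 18.5–25 / 25–30 / ≥30), and feeds the
category into the diabetes stage.

Two Monte Carlo modes, both first-class because either reading of
"simulating the model 1000 times" is defensible:

* **outcome-draw** (default): each replicate re-draws every individual's
  binary outcomes; each tract's realized prevalence is recorded. Replicate
  variance for independent individuals is the Poisson-binomial value
  `Σ pᵢ(1−pᵢ)/m²`.
* **coefficient-draw**: each replicate perturbs every coefficient (and
  intercept) by an independent normal draw at its standard error and
  records each tract's mean predicted probability (upstream states
  integrated out). Requires fitted standard errors; ingested published
  models have none and are rejected in this mode.

Default 1000 replicates; every replicate uses a substream derived from
(seed, mode, replicate index), so results are independent of evaluation
order. Upstream smoking/alcohol are carried from the synthetic population
by default (mode (b)); drawing them from upstream models per replicate
(mode (a)) is supported in outcome-draw mode.

## 4. Summaries, evaluation, export

Per tract × outcome: mean prevalence, 2.5/97.5 percentile interval (numpy
linear interpolation), and coefficient of variation = sample standard
deviation (n−1) over mean (defined 0 when the spread or mean is zero).
Percentile intervals were chosen because no interval formula is implied by
a Monte Carlo design; normal-approximation intervals would understate
asymmetry near 0/1. Citywide estimates weight each tract's replicate by its
eligible population, which conserves pooled prevalence exactly.

Evaluation against external estimates uses closed-interval 95% CI overlap
(a shared endpoint counts); the packaged reference table carries published
citywide/statewide prevalences with their intervals, in percent. Tract
rankings sort by mean prevalence with ties broken by tract id and can flag
a user-supplied priority set against the citywide mean. Map export writes
one GeoJSON FeatureCollection per outcome (prevalence, interval, CV as
properties); tracts without geometries are warned about and omitted. No
cartographic styling is bundled.

## 5. The synthetic-data generator

The generator emulates the *structure* of the real inputs, not any real
city:

* **Ground truth**: households per tract with sizes 1+Poisson(mean−1),
  default mean 2.4; the first member is always an adult, later members are
  children with a per-tract probability; members inherit household
  race/ethnicity and ancestry with probability 0.9. Ages are drawn uniform
  within bands (0–17, 18–29, …, 80–99; the under-21 adults exercise the
  eligibility filter). Category profiles vary across tracts along three
  independent smooth spatial axes (age structure, socioeconomic status,
  ethnic composition; golden-angle phased so no two axes are collinear),
  giving distinct tract-level patterns per outcome the way real cities
  show them. Magnitudes span realistic within-city contrasts (e.g.,
  less-than-high-school share roughly 10–42%, owner occupancy 25–65%).
* **Generating models**: a known chain smoking (ever, then current among
  ever — two nested binaries, since the upstream source for these fields
  is unspecified) → alcohol → exercise → fruit/veg → BMI (Gaussian
  residual, default sd 4.5 kg/m²) → diabetes. Signs follow the
  epidemiology; magnitudes are deliberately strong enough that every
  truly-nonzero block is detectable at the reference survey size, and each
  downstream stage has exactly one structurally-zero candidate block
  (fruit/veg: alcohol; BMI: race/ethnicity; diabetes: education) so
  selection has something real to remove. Intercepts are set so citywide
  adult marginals sit near published city levels (≈65% exercise, ≈18%
  fruit/veg, ≈11% diabetes, mean BMI ≈27).
* **Derived inputs**: constraint tables are exact tabulations of the truth;
  the microdata sample keeps whole households with tract labels stripped
  (independent household inclusion at the stated fraction); the survey
  samples adults without replacement and draws all behavior/outcome fields
  through the generating chain.
* **Toy city**: a 4-tract preset with single-person households and few
  occupied categories. Single-person households keep the swap move's fixed
  household cardinality consistent with the household-level table totals,
  which makes an exact TAE = 0 reconstruction *feasible* — the property the
  self-recovery check needs.

What the generator does **not** emulate: survey design effects
(stratification, weighting, nonresponse), measurement error in
self-reported outcomes, undercounted subpopulations (e.g., undocumented
residents, non-English speakers), within-tract spatial structure, and
migration between data vintages. Passing tests therefore demonstrate that
the pipeline recovers what the data-generating process encodes — not that
real survey extracts are free of these additional error sources.

## 6. Problem sizes and numerical choices

The default synthetic city is 31 tracts × 400 households (≈30,000
residents, ≈24,000 aged 21+) with a survey of n = 15,814 — the tract count
and survey size of the reference analysis at roughly a third of the
person-scale, keeping a full pipeline run around half a minute. Tolerances:
1e-8 on fit convergence (checked against closed-form and pseudo-inverse
oracles at 1e-6/1e-8), 1e-6 on calibration, exact arithmetic on
tabulations. Degenerate inputs (empty person targets, constant responses,
rank-deficient designs, non-finite BMI, malformed intervals) raise typed
errors naming the offending variable or category.

All randomness flows from one master seed through SHA-256-derived 31-bit
substream seeds labeled by stage (and tract or replicate), so any stage can
be re-run in isolation, tract work is order-independent, and two runs with
the same configuration and seed produce byte-identical outputs (the run
manifest records the config hash, per-stage seeds, package version and a
digest of every output file).

## 7. Known limitations

* The annealer optimizes each tract independently; households may be
  cloned into several tracts, and no cross-tract consistency with a
  citywide total is enforced beyond what the per-tract tables imply.
* The proposal move preserves household cardinality, so with multi-person
  households an unlucky initial draw bounds how exactly the household-level
  tables can be matched; restarts mitigate but do not remove this.
* Backward selection inherits the usual caveats of stepwise procedures
  (post-selection inference is not corrected; retained-model SEs are
  conditional on selection).
* Fixture-mode predictions inherit the published table's unstated BMI
  scale and its city-specific covariate coding; calibration fixes marginal
  levels, not associations.
* Chain calibration matches citywide marginals; tract-level levels are
  then fully determined by the model and the synthetic population, and are
  only as good as both.
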