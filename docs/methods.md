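# Methods

This note records the models, conventions and numerical choices behind
`visionair`, in the order of the analysis chain.

## Cohort model and derived labels

A cohort is a pandas DataFrame validated against the packaged schema
(`src/visionair/data/schema.yaml`), which fixes column names, types,
units, categorical level sets and the Demog/Habit/Environ feature-group
map. UCVA is on the 5-point logarithmic chart and constrained to
[3.0, 5.3]; NDVI to [−1, 1]; pollutants and nightlight are non-negative.

Derivations:

* spherical equivalent SE = sphere + cylinder/2 (diopters);
* screening myopia: SE ≤ −0.50 D **and** UCVA < 5.0; the SE boundary is
  inclusive;
* high myopia: myopic with SE ≤ −6.00 D (the −6.00 boundary is assigned
  to *high*; configurable via the module constant);
* school level: *senior* = middle or high school, else *primary*.

One UCVA/sphere/cylinder triple is modelled per student. When per-eye
measurements are available, `combine_eyes` takes the worse (lower-UCVA)
eye, the conservative screening convention; this is an assumption, since
cohort summaries are often reported over both eyes.

Missing data: categoricals get an explicit `missing` level; numerics are
median-imputed with a paired `<col>__missing` indicator column that
inherits the parent's feature group. This keeps every row and is
reversible. Categorical predictors are encoded as unordered factor codes
with attached level maps and **no normalization** of numeric features, so
tree models can split on level subsets and coefficients/attributions stay
in chart units.

## Synthetic cohort generator

The generator (`synthetic.py`, defaults frozen in
`data/default_cohort.yaml`) emulates a large Tianjin school-screening
cohort. The default conditions:

* categorical marginals equal the published cohort's category counts
  (school stage 70.1/21.1/8.8%, male 51.9%, parental myopia 64.5%, …);
* NO₂ ~ N(36.5, 1.8) and PM₂.₅ ~ N(38.3, 1.2) µg/m³, truncated at 0, with
  correlation ρ = 0.5 through a shared Gaussian factor (co-emission; makes
  the joint-vs-single scenario distinction meaningful); NDVI is a Beta(2,3)
  scaled to [0.15, 0.40]; nightlight lognormal (median ≈52 nW·cm⁻²·sr⁻¹);
* latent UCVA = base + Σ effects + interaction + N(0, noise_sd), clipped
  to [3.0, 5.3]. Effect signs: senior stage, parental myopia, female sex,
  homework, eye rubbing, close reading, nightlight, NO₂ and PM₂.₅
  negative; sleep, outdoor time, ball games, green-space visits and NDVI
  positive; transportation, salt and seafood intake are deliberate null
  features (useful for dummy-axiom checks). Pollutant effects are
  β_NO₂ = −0.010 and β_PM₂.₅ = −0.012 chart units per µg/m³, multiplied by
  a school-stage factor {primary 1.25, middle 0.6, high 0.5} — younger
  eyes more exposure-sensitive. `noise_sd` = 0.30 chart units, chosen so
  the irreducible error sits at the scale of the published model's test
  RMSE (≈0.30);
* sphere is back-filled from observed UCVA through a monotone map
  (linear in UCVA with a quadratic steepening below chart 4.5) plus
  N(0, 0.8) noise; cylinder is a small negative half-normal (|cyl| ≤ 1.5 D)
  and sphere = SE − cyl/2 by construction. The map's constants were
  calibrated once, numerically, so derived screening-myopia prevalence is
  ≈53% (±2 points at n = 20,000) with a usable high-myopia stratum (≈5%)
  and <1% of rows touching the chart bounds — the latter keeps the
  *unclipped* latent mean (`true_expected_ucva`) valid as a test oracle;
* missingness: per-column independent blanking at the published missing
  rates (BMI 3.8%, homework 3.9%, outdoor 4.8%, sleep 3.2%, NDVI 0.15%);
  outcome columns are never blanked.

What the generator does **not** emulate: spatial/school clustering of
exposures, measurement rounding (UCVA and refraction are continuous
here), age as a separate variable, longitudinal structure, and any real
joint dependence beyond the single pollutant correlation and the one
stage × pollutant interaction. Passing recovery tests therefore shows the
pipeline recovers *this* ground truth faithfully, not that the published
effect magnitudes are correct.

`analytic_clean_air_delta` gives the closed-form expectation of the
donor-resampling counterfactual under the generator's linear pollutant
effects: Δᵢ = Σ_p β_p · mult(stage_i) · (donor_mean_p − x_{ip}). The
fitted-model delta is compared against it in the acceptance suite (±30%).

## Model selection

Candidates are sklearn-style estimators carrying a `name`; the default
roster is

* `gbm` — least-squares stagewise gradient boosting of depth-limited
  trees (sklearn's histogram implementation behind the wrapper): native
  categorical level-subset splits on the factor codes, missing values
  routed to the lower-training-loss child, no early stopping, fixed tree
  count (300 × depth 6 × lr 0.1 by default) for reproducibility.
  `learning_rate=0` degenerates to the training-mean predictor;
* `random_forest` — bagged trees (factor codes consumed ordinally);
* `ridge` — ridge on one-hot factors.

The 80/20 split is simple random, unstratified, seeded; the test set gets
⌊n/5⌋ rows. Selection minimizes **test** RMSE (the criterion is stated
over the training distribution, but test behaviour is what the analysis
narrative rewards), ties broken by lower RMSEu then name.

Metric conventions: the systematic/unsystematic split uses the OLS line
of predictions on observations (Willmott's convention), which makes
RMSEs² + RMSEu² = RMSE² an exact identity; d is defined as 1 when its
denominator vanishes (constant, perfectly predicted series). With
constant observations the OLS slope is set to 0 and the intercept to the
prediction mean.

A finding worth knowing: on the default synthetic cohort the generative
structure is dominantly additive, so the ridge candidate can legitimately
win test RMSE while being structurally unable to represent the
stage × pollutant interaction. The pipeline honestly reports whichever
model wins; the acceptance script additionally computes the
attribution/counterfactual quantities on the boosted-tree model of
record, which is the interaction-capable model the explainable-analysis
design is built around. On real cohorts, where nonlinearities are
stronger, tree models win outright.

## Shapley attribution

The value function is interventional (marginal) with an explicit
background sample: v(S) is the mean model prediction over background rows
with the features in S replaced by the explained instance's values. This
is model-agnostic and matches the subset-substitution formula literally;
it is **not** the path-dependent tree-internal algorithm of common SHAP
tooling, so per-feature magnitudes can differ from implementations using
that algorithm even on identical models. Correctness is anchored in the
axioms (efficiency/additivity, dummy, symmetry) and in a brute-force
enumeration oracle in the test suite, not in replicating any third-party
tool's numbers.

* Exact estimator: full 2^|N| subset enumeration, default cutoff 12
  features (2¹² masks × background size evaluations per instance).
* Sampled estimator: uniform random feature orderings, each paired with
  one background row and also walked in reverse (antithetic pairing,
  which halves ordering variance and is *exact* for additive models);
  per-feature Monte-Carlo standard errors come from the spread of
  pair-averaged marginal contributions. The reported base value φ₀ is the
  mean prediction over the background rows actually drawn, which keeps
  φ₀ + Σφ = f(x) an exact identity for the sampled estimator too.
* Defaults in the pipeline: background = 100 seeded training rows,
  explanations on the first 500 cohort rows (train+test; the explained
  slice is configurable).

Mean |SHAP| is the per-feature mean absolute contribution over the
explained instances. The beeswarm export min–max scales raw feature
values to [0, 1] for colouring (categorical levels first mapped to evenly
spaced codes; constant features get 0.5).

## Subgroup explanations and partial dependence

Subgroup aggregation averages per-feature contributions over members, so
the subgroup mean prediction equals φ₀ plus the summed means exactly
(linearity). Group shares divide each group's **absolute** summed mean
contribution by the total absolute contribution (×100), reporting the
sign of the group's net contribution alongside — signed magnitude-shares;
the absolute shares sum to 100 by construction. Default subgroups: school
vs high myopia, primary vs senior, plus the whole cohort.

Partial dependence is the brute-force marginal (feature pinned to each
grid value, predictions averaged over all rows), numeric grids spanning
the 1st–99th percentiles in 20 points, categorical grids over observed
level codes, with per-point prediction spread reported. It
cross-validates against sklearn's brute-method implementation in tests.

## Clean-air counterfactual

Donor pool: rows at or below the pollutant's empirical 20th percentile
(ties included). For the joint scenario the pool is the union of each
pollutant's own low tail, and the (NO₂, PM₂.₅) **pair** is drawn from a
single donor row, preserving their covariance; the non-intervened
environmental features keep the individual's observed values.
Draws are uniform with replacement; t = 500 by default. Each individual
owns an independent substream (CRC32 of seed:id), so results are
invariant to row order. A singleton pool short-circuits to a single
deterministic evaluation.

The baseline is the model prediction on observed features. Reports give
per-stratum (all / primary / senior / school-myopia / high-myopia) means,
deltas and UCVA histograms on a 0.1-chart-unit grid. The exposure
gradient segments the pollutant into 20 equal-frequency bins (reduced
with a warning if distinct values run short), uses each bin as the donor
pool, and fits a per-stratum OLS slope of mean counterfactual UCVA on
bin-mean pollutant; both donor-pool means and medians are reported since
either may be quoted as the "clean" level.

## Pipeline, determinism and problem sizes

All stage seeds derive from the single run seed via `SeedSequence` spawn,
and CSV artifacts are byte-reproducible for a fixed config; stage wall
times are recorded in the manifest but excluded from the config hash and
from determinism comparisons. Default pipeline size is n = 5,000 with
t = 200 scenario draws and sampled SHAP on 500 instances; the acceptance
script uses n = 10,000, t = 200, 20 gradient bins at t = 10 per bin, and
the test suite uses smaller sizes per test. These sizes were chosen to
keep each run in the minutes range on a single CPU while leaving
Monte-Carlo error far below the effect sizes probed.

## Known limitations

* The interventional value function evaluates models off the data
  manifold (correlated features are broken up); shares and attributions
  inherit that standard caveat.
* No uncertainty is attached to SHAP values beyond Monte-Carlo error, nor
  to group shares.
* The counterfactual is predictive, not causal: it propagates the fitted
  model's associations under an exposure substitution and claims no
  confounding adjustment beyond the covariates in the model.
* The generator's dependence structure is a convenience, not an estimate
  of any real city's joint distribution.
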