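# visionair

Explainable machine-learning analysis of school children's **uncorrected
visual acuity (UCVA)** and ambient air quality — for epidemiologists and
vision-health researchers who want to weigh modifiable environmental
exposures (NO₂, PM₂.₅, greenness, nightlight) against demographic and
lifestyle drivers of childhood myopia, and to quantify how much vision
would improve under cleaner air.

UCVA is measured on the Chinese 5-point logarithmic chart (≈3.0–5.3;
5.0 ≈ decimal 1.0). The analysis chain is:

1. **Cohort model** — one row per student: demographic (school stage,
   parental myopia, sex, BMI), habit (sleep, homework, outdoor time, …)
   and environmental (nightlight, NDVI, NO₂, PM₂.₅) predictors plus ocular
   outcomes. Spherical equivalent SE = sphere + cylinder/2; screening
   myopia = SE ≤ −0.50 D with UCVA < 5.0; high myopia = SE ≤ −6.00 D.
2. **Model selection** — candidate regressors f̂ ∈ F (gradient-boosted
   trees, bagged trees, ridge on one-hot factors) fitted on an 80/20
   split; f\* = argmin of test RMSE, ties broken by lower unsystematic
   RMSE. Scores: RMSE, its systematic/unsystematic decomposition from the
   OLS line of predictions on observations (RMSEs² + RMSEu² = RMSE²), and
   Willmott's index of agreement d ∈ [0, 1].
3. **Shapley attribution** — interventional SHAP values
   φ_p(f\*, xᵢ) = Σ_{S⊆N∖{p}} |S|!(|N|−|S|−1)!/|N|! · (v(S∪{p}) − v(S)),
   with v(S) the mean prediction over a background sample with the
   features in S set to the instance; exact subset enumeration up to 12
   features and an antithetic permutation-sampling estimator with
   Monte-Carlo standard errors beyond that. Global importance is
   mean |SHAP|: I_p = (1/m) Σᵢ |φ_p(f\*, xᵢ)|.
4. **Subgroup explanations** — the subgroup mean prediction decomposed as
   f̄\*(D_K) = φ₀ + Σ_p mean φ_p over members, with Demog/Habit/Environ
   contribution shares, waterfall exports, and partial dependence curves.
5. **Clean-air counterfactual** — ȳ_DRᵢ = (1/t) Σⱼ f\*(x_demogᵢ, x_habitᵢ,
   x_environ∖{p}ᵢ, x_pʲ ∈ D_R): each student's pollutant value is resampled
   t times (default 500) from the donor pool D_R, the lowest-exposure 20%
   of the cohort, and predictions are averaged. Three interventions
   (NO₂-only, PM₂.₅-only, both as a joint pair draw), per-stratum benefit
   reports, and a 20-bin equal-frequency exposure gradient with
   per-stratum slopes.

Because the underlying screening cohort is not redistributable, the
package ships a **synthetic cohort generator** whose marginals are
calibrated to the published cohort summaries (myopia prevalence ≈53%,
70/21/9% primary/middle/high school, NO₂ ~ N(36.5, 1.8) µg/m³, PM₂.₅ ~
N(38.3, 1.2) µg/m³ with ρ = 0.5 co-emission correlation, NDVI ≈ 0.15–0.40)
and whose UCVA generative function has known effect signs and a
school-stage × pollutant interaction — so every downstream stage is
testable against ground truth.

## Worked example

```python
from visionair import RunConfig, run_pipeline, summarize_run
cfg = RunConfig(n=2000, seed=7, outdir="run7",
                shap={"max_instances": 300, "n_permutations": 16},
                scenario={"t": 100, "gradient_t": 10, "n_bins": 10})
run_pipeline(cfg)
print(summarize_run("run7"))
```

which prints (abridged):

```
selected model: ridge (test rmse=0.2980, rmse_s=0.2410, rmse_u=0.1754, d=0.7014, n=400)
top features by mean |SHAP|:
  school_type: 0.1603
  parental_myopia: 0.0353
  sex: 0.0334
  nightlight: 0.0272
  outdoor_hour: 0.0226
clean-air scenario deltas (chart units):
   no2_only |           all: 4.4826 -> 4.5137 (delta +0.0311, n=2000)
  pm25_only |           all: 4.4826 -> 4.5181 (delta +0.0355, n=2000)
       both |           all: 4.4826 -> 4.5258 (delta +0.0433, n=2000)
       both |       primary: 4.6035 -> 4.6460 (delta +0.0425, n=1417)
```

Reading the output: school stage dominates UCVA variation (mean |SHAP|
≈0.16 chart units), parental myopia and sex follow; replacing every
student's pollutant exposures with draws from the cleanest-20% pool lifts
mean UCVA by ≈0.03–0.04 chart units. On this synthetic cohort the
generative structure is mostly additive, so the ridge candidate can win
test RMSE; restrict the roster (`candidates: {roster: [gbm]}`) to explain
the boosted-tree model, which additionally captures the school-stage ×
pollutant interaction (younger children more sensitive to exposure
changes — steeper gradient slopes for primary students).

The same pipeline is scriptable from the shell (`visionair run --n 2000
--seed 7 --outdir run7` with paper-scale defaults t = 500 and 500
explained instances, then `visionair summarize run7`; the verbs
`generate`, `validate`, `fit`, `explain` and `scenario` run the
corresponding stages on their own).

All stage outputs land in the run directory as CSV/JSON artifacts
(fit reports, explanations, beeswarm table, subgroup waterfalls, group
shares, partial dependence curves, scenario results, gradient slopes) with
a manifest; a rerun of the same config reproduces them byte-for-byte.

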