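# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the tests demonstrate.

## The z-score event-sequence mixture

A *subtype* is a strict ordering `S` of abnormality events, where an event
is one biomarker crossing one z-threshold (1, 2 or 3 control SDs). With 13
biomarkers and three thresholds the grid has E = 39 events and stages
k = 0..39; stage 0 means no abnormality (figures conventionally show
patients on 1..39). The expected z of biomarker *i* at stage *k* is
piecewise-linear through (0, 0), the biomarker's threshold events at their
1-based sequence positions, and (E, z_max); when the biomarker's last
event occupies position E the terminal control point is dropped. z_max
defaults to 5 — it only needs to exceed the top threshold 3; the exact
value shapes the post-severe tail of trajectories and is configurable.

Emission noise is Gaussian per biomarker. The library default is
sigma = 1, the natural unit for control-referenced z-scores. When the data
come from the packaged generator, whose patient-level measurement
dispersion around the planted trajectory is `noise_scale` (default 0.5),
analyses use sigma = noise_scale: the emission scale is then correctly
specified, and with it the mixture likelihood is maximised at the planted
structure. This matters: with sigma = 1 on 0.5-dispersion data, EM started
*at* the planted truth migrates to a genuinely higher-likelihood but
wrongly-partitioned solution, so matching the emission scale is a
modelling decision, not a tuning knob.

Stages use a uniform prior over 0..E. Within one biomarker the threshold
events are constrained to appear in increasing order; every optimizer and
sampler move preserves this.

### Fitting

* Single-sequence optimization: multi-start greedy reinsertion — remove
  each event and re-insert it at its best admissible position until no
  move improves the (optionally per-visit-weighted) log-likelihood.
  Default 25 random starts; the scaled-down profile used by the test
  suite uses 3–5.
* Mixture: hierarchical EM. The c-subtype model is initialized from the
  (c−1)-subtype model by splitting each cluster with a two-subtype
  mini-EM on the cluster's own visits (random bipartitions, single-start
  half fits) and keeping the best split after full EM. E-steps are soft
  responsibilities; M-steps re-optimize each sequence on
  responsibility-weighted data (a generalized EM with a bounded number of
  reinsertion sweeps per iteration — every accepted move increases the
  EM Q-function, so the total log-likelihood is non-decreasing).
  Convergence: change < `em_tol` (default 1e-4; the fast profile uses
  0.01) or `em_max_iter`.
* MCMC: Metropolis–Hastings; the proposal moves one uniformly chosen
  event of one uniformly chosen subtype to a uniformly chosen admissible
  position (symmetric). Fractions are not sampled; they are refreshed
  each iteration by responsibility re-normalization (the alternative —
  sampling fractions — would widen fraction uncertainty but not change
  sequence posteriors materially). Default 100,000 iterations, 10%
  burn-in, thinning 10; the test profile uses 5,000–60,000.
* Numerics: likelihoods are computed in log-space; the batched candidate
  evaluation uses one BLAS product plus a fused max/exp/sum kernel
  (numba when importable, plain numpy otherwise; both paths agree to
  ~1e-12). Ties everywhere resolve to the lowest index; all stochastic
  steps derive from one seed.

### Model selection and agreement

Leave-one-dataset-out: each contributing study is held out once; models
with 1..C_max subtypes are fitted on the rest and scored by held-out total
log-likelihood. The selected C maximises the *summed* held-out
log-likelihood (the aggregation rule is a package choice; ties go to the
smaller C), and the final model is refitted on all datasets. Cross-fold
agreement: subtypes are aligned between fold pairs by exhaustive bijection
search (exact for C ≤ 4), then the Bhattacharyya coefficient of the
event-position posteriors is averaged over events (the averaging unit is a
package choice) and summarised as mean ± SD over fold pairs.

## The synthetic cohort generator

Real pooled-trial MRI tables are not publicly distributable, so the
package ships a generator that emulates their statistical structure; its
defaults define the study conditions used throughout the tests.

* 18 features: 10 regional volumes (ml), 7 regional NAWM T1/T2 ratios,
  total T2 lesion volume (ml). Control means/SDs are plausible adult
  values (e.g. deep grey matter 31 ± 2.5 ml); they are documented
  constants, not population claims. Controls depend on TIV, sex, age and
  age² through per-feature coefficients, with N(0, control_sd) residuals.
* 13 features are planted as disease-affected: six GM volumes, six NAWM
  T1/T2 ratios, lesion volume. The remaining five follow the control law
  in patients, so the Cohen's-D screen has a planted answer (13).
* Three subtypes with fractions 0.43/0.32/0.25 and qualitatively distinct
  orderings: cortex-led (cortical atrophy → lesions → NAWM), NAWM-led
  (corpus callosum/cingulate T1/T2 first), lesion-led (lesion accrual and
  deep GM atrophy first). Sequences are built deterministically from
  per-subtype feature priority lists with staggered thresholds.
* Baseline stages are truncated-geometric with per-subtype p =
  (0.038, 0.0445, 0.0253), giving mean baseline stages ≈ 14.5/13.8/16.2
  (lesion-led highest). Stage advances at 0.2/0.3/0.65 stages/year with
  stochastic rounding (one uniform per subject: unbiased, monotone within
  subject — deterministic rounding would floor the smaller rates to zero
  over annual visits).
* Affected features sit at the normative prediction displaced by
  (expected trajectory z) × control SD — negative for volumes and T1/T2,
  positive for lesion volume — plus N(0, (noise_scale · control_sd)²)
  measurement noise; so measured patient z ≈ planted z +
  noise_scale · N(0, 1). Dataset offsets (0, +0.1, −0.1 control SDs) are
  added per pseudo-trial.
* Clinical coupling. Baseline EDSS = 1.5 + 0.13 · stage + subtype offset
  (0/−0.3/+0.5) + N(0, 0.5), rounded to the 0.5 lattice, clipped to
  [0, 10]. At each follow-up year EDSS jumps by the subject's
  progression threshold with probability p_c · m(arm): p =
  (0.20, 0.20, 0.26) plants a discrete-time CDP hazard ratio of 1.3 for
  the lesion-led analogue, and the treated-arm multiplier
  (1, 1, 0.34) plants a −66% EDSS-slope treatment response there.
  Because jumps recur, the mean EDSS trajectory is linear in time and the
  mixed-model slope ratio is unbiased. Relapses between visits are
  Poisson with rates (0.25, 0.25, 0.55)/year (× arm multiplier);
  contrast-enhancing lesion counts are Poisson with means
  (0.93, 0.51, 2.28).
* One RNG stream per table, derived from the master seed, so controls and
  patients regenerate independently and byte-identically.

What the generator does **not** emulate: scanner/centre effects beyond
additive dataset offsets, missing data, relapse-proximal EDSS inflation
(visits are scheduled, so the "EDSS ≥ 1 month after relapse" rule is
satisfied by construction), floor/ceiling artefacts in raw feature scales
(values are not clipped), and any image-level process. Passing tests
therefore demonstrate correctness of the statistical machinery under
these idealised conditions, not performance on real trial data.

## Normative z-scoring

Per feature, ordinary least squares of the control values on
(1, TIV, sex, age, age²) — the flat-prior posterior mean, which coincides
with a Bayesian fit's point predictions. Residual SD uses denominator
n − 5. Patient z = (residual − mean control residual) / control residual
SD, sign-flipped for volumes and T1/T2 so higher z is worse; lesion volume
is not flipped. Feature screening keeps |Cohen's D| > 0.5
(patients-at-baseline vs controls, on adjusted values); when a region's
volume and T1/T2 both pass, grey-matter regions keep the volume and
white-matter regions the T1/T2 (the two are strongly correlated within a
region). Baseline = earliest visit per subject, ties by row order.

## Clinical endpoints

* CDP: threshold 1.5/1.0/0.5 EDSS points for baselines 0 / 0.5–5.5 /
  > 5.5; an onset qualifies when the increase is sustained at every
  subsequent visit up to and including the first visit ≥ 168 days later
  (the strictest reading; `require_all_interim=False` relaxes to the
  confirming visit only). Unconfirmable worsening censors at the last
  visit.
* Log-rank and Cox fits delegate to lifelines; tertiles use inverted-CDF
  empirical cuts with ties to the lower stratum; annualized relapse rate
  is Σ relapses / Σ person-years with the SE from a per-group Poisson GLM
  with log person-years offset (all-zero groups short-circuit to SE 0);
  the concordance index is implemented natively (pairs comparable when
  the smaller time is an event; risk ties count ½) and cross-checked
  against lifelines in the tests.
* Treatment response: per subtype, MixedLM EDSS ~ arm + time + arm:time
  with a random intercept per subject; response =
  100 · (slope_treated − slope_placebo)/slope_placebo with a delta-method
  SE; flagged undefined when |placebo slope| < 0.01 EDSS/year. The
  dataset-level random effect is omitted by default (the generator puts
  no dataset effect in EDSS); annual stage change averages per-subject
  least-squares slopes.

## Problem sizes

The packaged fixture is 500 controls and 2,000 patients across 3
pseudo-trials with 3 annual visits. Subtype-count cross-validation runs on
baseline visits with 3 folds, candidates 1–4, and reduced optimization
settings (5 starts, 15 EM iterations at tolerance 0.01); survival and
treatment-response recovery use a 2,000-patient cohort with 5 annual
visits so enough confirmed progressions accrue for stable Cox estimates.
The full-scale configuration (25 starts, 100,000 MCMC iterations,
candidate counts to 4) is available behind the `full` profile.

## Known limitations

* Visits are staged independently; no within-subject longitudinal
  coupling in the likelihood (stage slopes are estimated post hoc).
* No missing-biomarker marginalization: z-score tables must be complete.
* The uniform stage prior is misspecified relative to any real stage
  distribution; with a correctly specified emission scale this did not
  bias recovery in the packaged conditions, but it contributes to the
  small downward bias (~0.04 stages/yr) observed in annual stage-change
  recovery near the stage boundaries.
* Cross-fold subtype alignment is exhaustive only for C ≤ 4 (greedy
  alignment above that).
* The EDSS jump process makes within-subject worsening monotone; real
  EDSS series fluctuate, so CDP detection under measurement noise is
  exercised by the unit tests' hand-constructed series rather than by the
  generator.
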