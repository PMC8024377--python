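# mssustain

MRI-based subtyping and staging of multiple sclerosis (MS) cohorts with a
z-score event-sequence mixture model, plus the clinical endpoint analyses
used to characterise the resulting subtypes.

MS is conventionally divided into clinical phenotypes (RRMS, SPMS, PPMS)
that correlate only loosely with the underlying pathology visible on MRI.
An alternative is to let the imaging define the subtypes: express each
patient's visit as a vector of control-referenced z-scores over regional
grey-matter volumes, normal-appearing white-matter (NAWM) T1/T2 ratios and
T2 lesion volume, and model the population as a mixture of **subtypes**,
each a distinct ordering of abnormality **events**, with each visit placed
at a **stage** along its subtype's sequence (Subtype and Staging
Inference, SuStaIn). This package implements that pipeline end to end for
long-format cohort tables, together with a seeded synthetic multi-trial
cohort generator that stands in for pooled clinical-trial data, which are
not publicly distributable.

## Model

For biomarker *i* with z-thresholds {1, 2, 3} and a subtype sequence *S*
(a permutation of the 13 × 3 = 39 events), the expected z-score at stage
*k* is the piecewise-linear curve through (0, 0), each threshold event at
its sequence position, and (E, z_max). A visit with z-vector **z** has
likelihood

```
p(z | S, k) = prod_i Normal(z_i ; g_i(k | S), sigma_i)
p(z)        = sum_c f_c * 1/(E+1) * sum_k p(z | S_c, k)
```

with mixture fractions *f_c* and a uniform stage prior. Sequences are
fitted by multi-start greedy event reinsertion inside an EM loop with
hierarchical cluster splitting (1 → 2 → … subtypes); posterior uncertainty
over sequences comes from Metropolis–Hastings MCMC; the number of subtypes
is chosen by leave-one-dataset-out cross-validated log-likelihood; and
agreement of sequence posteriors across folds is measured with the
Bhattacharyya coefficient.

Downstream, subjects are staged per visit and the package computes the
trial-style endpoints: 24-week confirmed disability progression (EDSS
increase of 1.5/1.0/0.5 points depending on baseline, sustained ≥ 24
weeks) with log-rank and Cox contrasts, annualized relapse rates,
Harrell's concordance index, per-subtype EDSS-slope treatment response
from a linear mixed model, annual stage change, and subtype stability.

## Worked example

```python
import mssustain as ms

config, controls, patients = ms.default_fixture()   # seeded synthetic cohort
norm = ms.fit_normative(controls)                   # covariate model on controls
sel = ms.select_features(controls, patients, model=norm)
Z = ms.compute_zscores(patients, norm, features=list(sel.retained))
print(len(sel.retained))                            # -> 13 (of 18 candidates)

grid = ms.build_event_grid(sel.retained)            # 13 x {1,2,3} = 39 events
opts = ms.SustainOptions(starts=5, sigma=config.noise_scale, seed=11)
model = ms.fit_sustain(Z, grid, 3, opts)
print(model.fractions.round(3))                     # ~ [0.44, 0.32, 0.24]

asg = ms.assign(Z, model)                           # per-visit subtype + stage
print(asg.table[["modal_subtype", "modal_stage"]].head())
```

Running `examples/05_clinical_endpoints.py` on the packaged cohort prints,
among other things:

```
24-week CDP, placebo arms: log-rank chi2 7.5, p 0.0234
  lesion-led vs cortex-led: HR 1.30 [1.05, 1.62]
annualized relapse rate (placebo arms):
  lesion-led 0.55 +/- 0.02 per year
lesion-led treatment response: -64% +/- 3% EDSS-slope change
```

i.e. the lesion-led subtype carries the highest progression hazard and
relapse rate, and is the subtype with a clear treatment response — the
clinical profile the generator plants and the endpoint code recovers.

Each script in `examples/` exercises one capability (simulation,
normative z-scoring, fitting, cross-validation, endpoints); a thin CLI
(`mssustain simulate|zscore|fit|cv|stage|endpoints|run`) wraps the same
functions for shell use.

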