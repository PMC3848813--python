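# casecohort

Derive and assess survival risk prediction models from **case-cohort**
data: weighted Cox pseudolikelihood estimation (Prentice, Self & Prentice,
Barlow schemes), weighted Breslow baseline hazard and absolute risk, and
design-adapted measures of predictive ability — the weighted Harrell
C-index, the weighted Royston–Sauerbrei D, and the net reclassification
improvement (NRI) with the correct exclusion rule — together with a
reproducible Weibull simulation benchmark comparing case-cohort estimates
to their full-cohort gold standard.

## Who this is for

Epidemiologists and biostatisticians analysing two-phase cohort studies in
which expensive covariates (biomarkers, genotypes) are measured only on a
random subcohort (sampling fraction α) plus all cases. Hazard ratios from
such data are routinely estimated with weighted Cox models; this package
additionally provides *unbiased discrimination and reclassification
metrics*, which the standard formulas get wrong under case enrichment.

## The statistics

With S(t|x) = S₀(t)^exp(βx), β is estimated by maximising the
pseudolikelihood Σ_events [βxᵢ − log Σ_{j∈R(tᵢ)} w_j e^{βx_j}] with
scheme-specific risk sets and weights (non-subcohort cases enter only at
their own event), robust sandwich SEs, and a 1/α-rescaled Breslow baseline
for absolute risk 1 − S₀(t)^exp(βx). Predictive ability:

* **Weighted C** — relevant pairs are split into case-case and
  case-control comparisons and the latter weighted 1/α:
  C_W = [n_c,1 + ½n_u,1 + (1/α)(n_c,0 + ½n_u,0)] / [n_r,1 + (1/α)n_r,0].
* **Weighted D** — weighted ranks (subcohort controls mass 1/α), Blom
  scores with the maximum weighted rank as effective n, scaled by √(π/8);
  D_W is the coefficient of the scores in a weighted Cox model.
* **NRI** — #events up − down over events plus #non-events down − up over
  non-events at a risk horizon t; no reweighting needed, but non-subcohort
  cases with events after t must be excluded (an 1/α-weighted alternative
  keeps them). Bootstrap SEs preserve the design structure.

Unweighted C and D applied naively to a case-cohort set are biased towards
the null — by ~18% and ~68% respectively at α = 0.03 under the benchmark's
high-incidence conditions — while the weighted versions track the full
cohort. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from casecohort import (draw_case_cohort, fit_weighted_cox, breslow_baseline,
                        predict_absolute_risk, weighted_c, generate_covariates,
                        simulate_cohort)
from casecohort.metrics import royston_d
from casecohort.study import chd_covariate_spec, chd_generating_model

spec = chd_covariate_spec()                      # age, smoking, SBP, chol, HDL
model = chd_generating_model(spec)               # Weibull calibrated to
                                                 # 10y/25y incidence .073/.277
x = generate_covariates(6773, spec, seed=42)
cohort = simulate_cohort(x, model, seed=7, covariate_names=spec.names)

design = draw_case_cohort(cohort, alpha=0.03, seed=11)   # 3% subcohort + cases
fit = fit_weighted_cox(design, covariate_names=("age", "smoking", "sbp", "tchol"),
                       scheme="prentice")
lp = fit.linear_predictor(cohort.covariate_matrix(("age", "smoking", "sbp", "tchol")))
c = weighted_c(lp, design)
d = royston_d(lp, design, scheme="prentice")
print(f"weighted C = {c.estimate:.3f} (se {c.se:.3f})")
print(f"weighted D = {d.estimate:.3f} (robust se {d.se:.3f})")
```

prints (exact values vary with the seeds)

```
weighted C = 0.660 (se 0.018)
weighted D = 0.954 (robust se 0.149)
```

— i.e. from a 3% subcohort the weighted measures recover the full-cohort
discrimination (C ≈ 0.667, D ≈ 1.00 on this realisation), where the naive
C and D would read ≈ 0.54 and ≈ 0.30. The `examples/` directory has one
narrative script per capability (simulation, weighted Cox, absolute risk,
discrimination, reclassification, benchmark sweep); a thin CLI
(`casecohort simulate|design|fit|evaluate|sweep`) wraps the same functions
for file-based workflows.

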