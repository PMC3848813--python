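# Methods

`casecohort` derives Cox-type risk prediction models from case-cohort
samples and assesses them with design-adapted measures of predictive
ability. This note records the statistical procedures, the defaults and the
reasoning behind the open design choices.

## The case-cohort design

A case-cohort study measures covariates on a random subcohort — a simple
random sample of the full cohort with sampling fraction α — plus every case
(subject with an observed event). Follow-up is known for the whole cohort,
covariates only for the case-cohort set (subcohort ∪ cases). The subcohort
is drawn as a fixed-size, without-replacement sample of size round(αN)
rather than Bernoulli(α) thinning: this matches the usual description of a
"random subsample with proportion α" and removes the extra variance of a
random subcohort size. Stratified subcohorts and competing risks are out of
scope.

The analysis time scale is time from study entry. Staggered entry matters
only through administrative censoring: with entry offsets E ~ Uniform(0, w)
and a study end at A calendar years, a subject is censored at A − E on the
analysis scale (option `censor_from_entry=False` censors everyone at A
instead).

## Weighted Cox pseudolikelihood

Hazard ratios are estimated by maximising

  l(β) = Σ_events [βx_i − log Σ_{j∈R(t_i)} w_j e^{βx_j}],

where risk sets R and weights w implement one of three schemes. A
non-subcohort case is never at risk before its own event:

* **Prentice** — subcohort members at risk, weight 1; the event subject
  joins its own risk set with weight 1 even if outside the subcohort.
* **Self & Prentice** — denominators are subcohort-only; non-subcohort
  cases contribute only numerator terms.
* **Barlow** — subcohort members at risk carry weight 1/α (so denominators
  mimic full-cohort totals); any subject at its own event time carries
  weight 1.

All three reduce exactly to the ordinary partial likelihood at α = 1; this
reduction is tested to 1e-8 and against an independent Cox implementation.

Numerics: covariates are centred internally (the partial likelihood is
invariant; the centring is folded back into predictions), ties are handled
with the Breslow approximation, and Newton–Raphson with step-halving runs
from β = 0 until the relative log-pseudolikelihood change is < 1e-9 and the
gradient max-norm < 1e-6 (cap 100 iterations). Risk-set membership is
evaluated by predicates (`exit ≥ t`), not by perturbing event times with an
ε, which avoids floating-point tie hazards. Coefficients exceeding |β| > 50
abort with a separation diagnosis. The source publications state no
tolerances or tie method; these are this package's choices.

Model-based SEs (inverse observed information) are not valid under
subcohort sampling. The robust covariance is the infinitesimal-jackknife
sandwich I⁻¹(Σᵢ UᵢUᵢᵀ)I⁻¹ over per-subject score residuals, each subject's
contributions aggregated across every risk set it enters with its scheme
weights — the grouped-DFBETA estimator that standard software computes as
the "robust" Cox variance — rather than leave-one-out refitting (O(np²)
versus O(n) full refits, identical to first order). At α = 1 it matches the
standard robust Cox variance; across repeated subcohort draws the mean
robust SE sits within 10% of the empirical SD in the test suite.

## Baseline hazard and absolute risk

The cumulative baseline hazard is a weighted Breslow step function
Λ̂₀(t) = Σ_{tᵢ≤t} dᵢ/D(tᵢ). For Prentice and Self & Prentice fits the
denominator is the subcohort sum rescaled by 1/α, which estimates the
full-cohort denominator; for Barlow the scheme's own weighted denominator
is already on the full-cohort scale and is used unchanged. Whether a
Prentice non-subcohort case should enter the denominator at its own event
is ambiguous in the literature; the default excludes it (the
Self–Prentice-type estimator), with a toggle that includes tied
non-subcohort cases at weight 1. The toggle guarantees strictly positive
denominators — at α ≈ 0.03 a late event occasionally finds zero subcohort
members still at risk — and the benchmark runner enables it for that
reason. Absolute risk by horizon t is 1 − S₀(t)^exp(βx) with
S₀ = exp(−Λ̂₀).

## Weighted C-index

Relevant pairs (the member with the strictly shorter observed time has an
event) are split into case-case and case-control comparisons; case-control
pairs are up-weighted by 1/α because controls are under-sampled:

  C_W = [n_c,1 + 0.5 n_u,1 + (1/α)(n_c,0 + 0.5 n_u,0)] / [n_r,1 + (1/α) n_r,0].

All cases are treated alike whether or not they are in the subcohort;
controls are non-case subcohort members. Ties: pairs with exactly equal
survival times are not relevant (no ordering is observed; the standard
Harrell convention), and predictor ties in relevant pairs earn half credit.
The implementation is vectorised chunked pair enumeration, verified exactly
against an O(n²) brute-force oracle and, unweighted, against an independent
implementation. The analytical SE is a leave-one-subject-out jackknife on
the weighted pair sums — the exact formula behind the published weighted
SEs is not stated, and the jackknife validates empirically (mean SE within
10% of the across-replicate SD at every sampling fraction tested) and
against the bootstrap.

## Weighted Royston–Sauerbrei D

D is the log hazard ratio between the model-defined higher- and lower-risk
halves of a cohort: rank the linear predictors, map ranks through Blom's
approximation Φ⁻¹((r − 3/8)/(n + 1/4)), scale, and take the coefficient of
the scores in a second Cox model. The scale factor is √(π/8) ≈ 0.627: this
is the constant that gives scores with variance π/8 and means of the
negative/positive halves of ∓0.5, which is what makes the coefficient
interpretable as a log hazard ratio between risk halves. (Published
descriptions sometimes write the factor as "π/8"; only the square root has
those two properties, so √(π/8) is implemented.)

For case-cohort data the ranks are weighted: each subcohort control
contributes mass 1/α and every case mass 1 along the predictor ordering; a
subject's weighted rank is the cumulative mass up to and including it, with
tied predictors averaging the cumulative mass over the tied block (the
ordering within a tied block is otherwise arbitrary). Blom's approximation
then uses the maximum weighted rank — approximately the full-cohort size —
as the sample size. The second-stage model is the weighted Cox
pseudolikelihood under the same scheme, with a robust SE; D_W is its
coefficient. At α = 1 the procedure is exactly the full-cohort D. For
normally distributed linear predictors with SD σ and light censoring,
D → √(8/π)·σ; this closed form is used as an independent oracle in the
tests. A constant predictor returns D = 0, flagged degenerate.

## NRI with the case-cohort exclusion rule

The NRI for adding a marker compares risk categorisation under two models:
NRI = (#events up − #events down)/#events + (#non-events down − #non-events
up)/#non-events, judged at a horizon t using absolute risks. Because the
movement proportions are computed within events and within non-events
separately, case-cohort sampling needs no reweighting of the formula
itself. What it does need is the correct eligible set: subjects censored
before t without an event are excluded (status unknown), and — specific to
the design — non-subcohort cases whose event falls after t are excluded,
since keeping them would enrich the "non-event" group with future cases
and inflate its risks. Subcohort members with events after t count as
non-events, exactly as in a cohort analysis.

Category boundaries are half-open upward ([0, 0.10), [0.10, 0.20),
[0.20, 1] for the default 10%/20% grid), so a risk equal to a boundary
falls in the higher category deterministically. Continuous mode counts any
strict change in predicted risk; exact ties move nobody.

An alternative formulation keeps the late non-subcohort cases in the
non-event portion and compensates by weighting subcohort controls 1/α;
its event portion is unchanged and it reduces exactly to the standard NRI
at α = 1.

The analytical SE is the binomial-difference form
SE² = [p_up,e + p_down,e − (p_up,e − p_down,e)²]/n_e + (same for
non-events)/n_ne. For case-cohort data it is knowingly anticonservative:
it ignores the sampling error of the risk estimates themselves, and in the
benchmark it understates the across-replicate SD at small α. The
design-preserving bootstrap (resampling with replacement separately within
the subcohort and within the non-subcohort cases, so every replicate is a
valid design with the same α and group sizes) is the recommended SE.

## Synthetic benchmark

The benchmark emulates a prospective CHD cohort of 6773 middle-aged men
with covariates age 52.3 (7.6) years, smoking prevalence 53.3%, systolic
blood pressure 141.8 (20.6) mmHg, total cholesterol 6.3 (1.0) mmol/l and
HDL-cholesterol 1.4 (0.2) mmol/l. Covariates are independent by default —
the source cohort's correlation matrix is not published — and a Gaussian
copula accepts a correlation matrix for sensitivity analyses. The
generating hazard ratios are the published five-covariate (HDL-including)
model's, per SD for continuous covariates (converted to per-unit by
dividing by the SD) and per category for smoking. A single generator
including HDL is used for all measures: the published continuous NRI for
adding HDL is far from zero, which requires HDL to carry a true effect.

Event times are Weibull with cumulative hazard H(t|x) = (λt)^γ e^{βx} —
the shape/rate parametrisation, λ = 1/scale — sampled by inversion,
T = (−log U · e^{−βx})^{1/γ}/λ. The rate form matters for the low-incidence
scenario: halving λ scales every cumulative hazard by 2^{−γ} ≈ 0.32 at the
calibrated shape. (A rate multiplying the hazard linearly could at most
halve a small incidence — concavity bounds the 10-year value below by half
the original — and could not reproduce the published low-incidence values;
the scale-form rate can and does.) Because the source's fitted (λ, γ) are
unpublished, they are calibrated so the marginal cumulative incidence —
estimated over a fixed 200 000-draw Monte Carlo sample of the linear
predictor — hits 0.073 at 10 years and 0.277 at 25 years (residuals
< 1e-4); with no covariates the calibration has a closed form used as a
test oracle. Entry is Uniform(0, 5) calendar years with the study closing
at year 25, so follow-up spans 20–25 years. The covariate matrix is drawn
once per scenario and reused across replicates (repeated outcome
realisations for one cohort); outcome and subcohort streams are re-seeded
per replicate, all deterministically from a base seed. The low-incidence
scenario halves the calibrated λ without recalibrating.

Each replicate: simulate outcomes; fit the four- and five-covariate models
on the full cohort and compute C, D and both NRIs (the gold standard); draw
the design; refit with the Prentice-weighted pseudolikelihood; recompute
every measure in naive and weighted form plus the mean 10-year
absolute-risk error over the case-cohort set. Aggregation reports means,
the percent bias of the naive measures (100·(full − naive)/full), the mean
analytical SE, the empirical SE (SD across replicates), and relative
efficiency as the full-to-case-cohort ratio of mean analytical variances
(RE) or empirical variances (ERE); figure outputs use empirical variances
for the NRI, whose analytical SE is unreliable here. The default is 100
replicates over fractions {0.03, 0.1, 0.3, 0.5, 0.9} (the reference scale
is 1000 replicates over 18 fractions; the config exposes both), chosen so a
full benchmark plus the test suite completes in minutes on one core.

### What the emulation does and does not show

Passing benchmarks demonstrate that the weighted estimators recover their
full-cohort counterparts under realistic marginals, incidence and
censoring. They do not exercise covariate correlation: with independent
covariates the fitted four-covariate linear predictor has SD ≈ 0.62,
slightly below the ≈ 0.66 implied by published full-cohort D values, so
the benchmark's D means run ≈ 0.07 low (C, which depends on ranks more
than spread, matches to < 0.01, as do both NRIs and all bias/efficiency
patterns). Real-data features not emulated: covariate correlation and
measurement error, non-proportional hazards, competing risks, and
non-administrative loss to follow-up.

## Known limitations

* Efron ties, time-dependent covariates, age-as-timescale models,
  stratified or multi-study designs, and competing-risks absolute risk are
  not implemented.
* The analytical NRI SE is reported but anticonservative for case-cohort
  data; use `bootstrap_se`.
* At very small α (≲ 0.03) weighted-D and coefficient estimates carry the
  slight upward bias intrinsic to the weighted second-stage Cox fit; the
  Prentice scheme is the least biased of the three and is the default.
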