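# Methods

This note documents the statistical models implemented in `psafatigue`,
the synthetic-trial generator that exercises them, the numerical choices
made where the design was genuinely open, and what the validation suite
does and does not demonstrate.

## Setting

A placebo-controlled parallel-arm PsA trial programme: two studies (`D1`,
`D2`), three arms (`Q4W`, `Q8W` active; `PBO`), visits at weeks
0, 4, 8, 16, 24 and every 8 weeks to 52. The primary outcome here is the
FACIT-Fatigue score (0–52, higher = less fatigue); the landmark for
responder and mediation analyses is week 24, the end of the
placebo-controlled period. Randomization is stratified by baseline
non-biologic DMARD use and, depending on the study, prior TNFi use (`D1`)
or baseline CRP > 2.0 mg/dL (`D2`).

## Synthetic-trial generator (`synthetic.py`)

Patient-level data are simulated because the source trials' patient data
are proprietary; the generator reproduces the *structure* the analyses
assume, with recorded ground truth.

**Baseline covariates.** Each study has fixed marginal distributions
(normal, lognormal for skewed measures, binomial for binary ones)
calibrated to the published per-study means/SDs — e.g. `D2` baseline FACIT
~ N(29.7, 9.7) truncated to [0, 52], CRP lognormal with median 1.2 mg/dL.
Covariates are drawn independently: the published tables report marginals
only, and independence keeps every structural coefficient interpretable.
Correlated covariates (e.g. pain with HAQ-DI) are a realism gap noted
under limitations.

**Mediators** are drawn at the landmark visit from explicit models in arm
and centred covariates: logistic for binary response endpoints
(ACR20: placebo rate ≈ 0.25, active log-odds shift 1.55, giving active
rates ≈ 0.60; MDA: ≈ 0.07 vs ≈ 0.22) and linear for the continuous
CRP change (arm shift −0.9 mg/dL, residual SD 1.2). These defaults put the
arm-wise response rates in the range reported for this class of trials.

**Outcome.** The landmark FACIT change follows

```
Δ24 = μ0 + θ_T·1[active] + θ_M·M + γ'(C − E[C]) + ε,   ε ~ N(0, σ²)
```

with defaults μ0 = 2 (secular/placebo improvement), θ_T = 2.5 FACIT
points (direct effect), θ_M = 3.2 per unit of the structural mediator
(ACR20 by default), a mild regression-to-the-mean term on baseline FACIT
(γ = −0.25/point) and σ = 7.5 points, matching the observed-change SDs of
8–10 points reported for such trials. Other visits scale the systematic
part by a linear ramp to week 24 (plateau after), and noise splits into a
patient intercept and visit-level error (50/50), giving within-patient
correlation for the MMRM to model. Dropout is monotone at 2%/visit
(missing-at-random); treatment-failure events are off by default and can
be injected via `apply_treatment_failure`, which resets the change to zero
from the failure week on (a conservative operationalisation of
treatment-failure rules, whose exact trial definitions are study-specific).

**Ground truth.** `SimulationTruth` records NDE = θ_T and
NIE = θ_M·(E[M(active)] − E[M(placebo)]), the expectation taken over the
covariate distribution — closed form for the linear mediator, Monte-Carlo
(200k fresh covariate draws, fixed internal stream, cached) for the
logistic ones. Only the designated structural mediator transmits effect;
the other mediators are generated for endpoint analyses and have true
NIE ≈ 0 by construction, which the mediation report on default data shows.

**Instrument bounds.** Baseline scores are truncated to [0, 52].
Post-baseline scores are *not* censored at the bounds: censoring would
break the exact linear structural model that the recorded truth, the
additivity identity and all recovery tests rely on (measured effect of
ceiling censoring: ≈ −0.1 point bias on NDE at the default noise level).
Real FACIT data are bounded, so the generator idealises the tail of
well-responding patients; conclusions about estimator behaviour near the
instrument ceiling cannot be drawn from these simulations.

## MMRM (`mmrm.py`)

Fixed effects: treatment, visit, treatment × visit, baseline FACIT score
and the two stratification factors (covariates centred at their grand
means, so LS means are the cell predictions directly). The residual
visit-by-visit covariance is unstructured, estimated by REML: the fixed
effects are profiled out and the restricted likelihood is maximised over a
log-Cholesky parameterisation with L-BFGS-B, grouping patients by
missingness pattern for vectorised evaluation. No imputation: incomplete
follow-up enters through the per-patient marginal likelihood
(missing-at-random). No installed Python routine fits this marginal
model (mixed-model packages do not expose an unstructured residual
covariance), hence the direct implementation; it is verified against
closed-form GLS/ANCOVA in the suite. Choices:

* **Start values**: per-week residual variances, zero covariances.
* **Fallback**: compound symmetry on non-convergence, flagged in the fit.
* **Degrees of freedom**: between-within — arm contrasts use
  df = (number of subjects) − (arms + between-subject covariates). This is
  the simplest defensible convention; Satterthwaite/KR approximations are
  out of scope and would change small-sample CIs only.
* **Singular designs** raise an error naming the aliased term.

## Responder statistics (`responders.py`)

Responder = change ≥ 4 points at week 24; missing landmark responses count
as non-responders (non-responder imputation, the conventional trial
reading). The CMH test uses the Cochran variance convention
(Σ n₁n₀m₁m₀/n³), under which the single-stratum statistic equals the
Pearson chi-square exactly; the Mantel–Haenszel hypergeometric convention
differs by (n−1)/n per stratum and is tied to ours in a cross-check test.
Zero-margin strata are uninformative and dropped with a log message. CIs
on proportion differences are plain Wald. Cumulative curves sweep integer
thresholds 0–20 with missing responses as non-achievers, so the curve at
threshold 4 equals the responder proportion by construction.

## Effect sizes (`effect_size.py`)

Cohen's *d* divides the observed mean change by the baseline SD of the
same randomized arm. Reported values round half-away-from-zero to two
decimals; magnitude labels use |d| with boundaries assigned upward
(0.50 → moderate, 0.80 → large), consistent with the published labelling
of 0.52 as moderate and 0.81 as large.

## Mediation (`mediation.py`)

Estimand: decomposition of the week-24 active-vs-placebo effect (each
active arm separately against placebo) into natural direct and indirect
effects under the standard no-unmeasured-confounding assumptions. Models:

* mediator: M ~ treatment + covariates — logistic (binary) or OLS
  (continuous), maximum likelihood;
* outcome: Y ~ treatment + M + covariates (+ treatment × M when the
  interaction flag is on), OLS.

The default covariate set is the twelve baseline measures: age, sex, BMI,
baseline FACIT score, CRP, PsA duration, physician global, patient global
(arthritis), HAQ-DI, pain, SJC, TJC. Complete-case analysis throughout.

Without interaction, NDE is the outcome-model treatment coefficient; NIE
is the product form — (outcome M-coefficient) × (mediator-model treatment
coefficient) for continuous M, or × the average over analysed patients of
invlogit(η | T=1) − invlogit(η | T=0) for binary M. With interaction, the
counterfactual-standardisation generalisations are used (NDE averages the
interaction term over each patient's control-condition mediator mean).
A Monte-Carlo counterfactual simulator — draw M(0), M(1) from the fitted
mediator model for resampled covariate rows, evaluate the fitted outcome
surface at Y(1, M(0)), Y(0, M(0)), Y(1, M(1)) — provides an independent
estimate of the same quantities and agrees with the formulas within Monte
Carlo error in the suite.

**Additivity.** NDE + NIE equals the treatment coefficient of the reduced
regression Y ~ treatment + covariates *exactly* (machine precision) when
the mediator model is linear — the omitted-variable identity. For binary
mediators the logistic marginalisation replaces the OLS projection and the
identity holds only approximately; the oracle check covers that case.

**Bootstrap.** Percentile CIs from patient-level resampling with
replacement, stratified by arm to preserve the allocation ratio; default
B = 1000; the reported point estimate is the full-data estimate, never the
bootstrap mean. Resamples with a degenerate binary mediator (all 0/1) or a
separated logistic fit are redrawn with a logged count. A fully noiseless
fixture cannot produce a zero-width CI for *both* effects: if mediator and
outcome equations are both noiseless the mediator is an exact linear
combination of the outcome design and the fit is singular; a noiseless
outcome alone gives an exactly degenerate NDE bootstrap distribution,
which is what the suite asserts.

**Inner fits.** The bootstrap and simulation loops refit the two models
hundreds of thousands of times, so they run on a compact IRLS/OLS engine
(`_glm.py`) solving the same ML problems; its estimates are checked
against statsmodels to ~1e-8 in the suite. Separation raises by default;
an optional ridge penalty (`logit_penalty`) is available as a fallback.

**Percent mediated** = 100·NIE/(NDE+NIE), complement percent direct,
reported to one decimal. When NDE and NIE have opposite signs the ratio is
still reported (outside [0, 100]) with a warning; a numerically zero total
leaves the percentages undefined and flagged.

## Validation suite and problem sizes

The simulation studies use these sizes, chosen to make Monte-Carlo error
small relative to the quantities checked while keeping a single-CPU run
short: oracle agreement at 10⁶ counterfactual draws (2-MC-SE criterion);
parameter recovery over 500 replicate trials at n = 1000/arm (observed
|bias| ≈ 0.02–0.03 FACIT points against a 0.1-point criterion); bootstrap
coverage over 500 trials at n = 300/arm with B = 500 (observed NIE
coverage 95.6%, criterion 92–98%). The MMRM recovery check runs at 20
replicates with a sampling-error-based tolerance; its exact closed-form
equivalences (ANCOVA, GLS) carry the correctness burden.

## Limitations

* Independent baseline covariates; no within-patient evolution of
  mediator components beyond the single landmark.
* The generator's mediator-to-outcome link is linear and single-mediator;
  joint mediation and exposure-induced mediator–outcome confounding are
  not simulated, so the suite validates the estimator under its own
  assumptions, not robustness to their violation.
* Post-baseline scores ignore the instrument ceiling (see above).
* Bootstrap type is percentile only; BCa is not implemented.
* MMRM degrees of freedom use the between-within convention; small-sample
  agreement with Satterthwaite-based software is not expected to be exact.
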