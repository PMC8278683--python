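# psafatigue

Statistical analysis chain for fatigue outcomes in parallel-arm psoriatic
arthritis (PsA) trials, built for biostatisticians who want to study — and
stress-test — how a treatment's effect on patient-reported fatigue
decomposes into direct and clinically mediated components.

Fatigue is measured with FACIT-Fatigue (0–52, higher = less fatigue;
a ≥4-point gain is clinically meaningful). The package covers the standard
analysis suite for a placebo-controlled trial of an active treatment given
every 4 or 8 weeks (arms `Q4W`, `Q8W`, `PBO`) in two studies (`D1`, `D2`):

* **MMRM** — mixed-effect model for repeated measures on change scores,
  with treatment × visit fixed effects, baseline-score and
  stratification-factor adjustment, and an unstructured visit covariance
  estimated by REML; reports LS means and active-vs-placebo contrasts.
* **Responder statistics** — ≥4-point responder proportions, stratified
  Cochran–Mantel–Haenszel tests, Wald CIs on proportion differences, and
  cumulative threshold-sweep curves (thresholds 0…20).
* **Effect sizes** — Cohen's *d* = (mean change)/(baseline SD), with the
  0.20/0.50/0.80 small/moderate/large convention.
* **Causal mediation** — the centrepiece. For a mediator *M* (ACR20 or MDA
  achievement, binary; change in CRP, continuous) fitted with
  *M* ~ treatment + covariates (logistic/linear) and a linear outcome model
  *Y* ~ treatment + *M* + covariates, the treatment effect splits into the
  natural direct effect (NDE) and natural indirect effect (NIE):

  ```
  NDE = θ_T                      (outcome-model treatment coefficient)
  NIE = θ_M · (E[M | T=1] − E[M | T=0])      (product / marginalisation form)
  total = NDE + NIE,   % mediated = 100 · NIE / total
  ```

  with percentile-bootstrap CIs (patient-level resampling stratified by
  arm), optional exposure–mediator interaction via counterfactual
  standardisation, and an independent Monte-Carlo counterfactual simulator
  used to validate the regression formulas.
* **Synthetic trial generator** — patient-level data with baseline
  covariates calibrated to the published two-study marginals, mediators
  drawn from explicit logistic/linear structural models, and landmark FACIT
  changes following a linear structural model whose true NDE/NIE are
  recorded, so every estimator can be checked against known ground truth.

## Worked example

```python
from psafatigue import (TrialConfig, generate_trial, prepare_mediation_data,
                        MediationSpec, bootstrap_mediation)

trial = generate_trial(TrialConfig(study="D2", seed=7))
data = prepare_mediation_data(
    trial.baseline, trial.visits, trial.mediators,
    mediator_name="ACR20", active_arm="Q4W",
)
result = bootstrap_mediation(data, MediationSpec("ACR20", bootstrap_reps=1000, seed=1))
```

This simulates a ~739-patient study, keeps the Q4W and placebo arms
(complete cases at week 24), and decomposes the week-24 effect through
ACR20 response. It prints:

```
true NDE/NIE:  2.50 / 1.14
NDE   2.75  (95% CI 1.26, 4.22)
NIE   1.02  (95% CI 0.53, 1.55)
total 3.77  (95% CI 2.28, 5.20)
% direct 73.0   % indirect 27.0
```

Read: of the estimated 3.77-point fatigue benefit, 1.02 points (27%) are
transmitted through the treatment's effect on ACR20 response and 2.75
points are direct — both CIs exclude zero, and the estimates bracket the
generator's true values (2.50 / 1.14).

## Analysis scripts

The `analysis/` drivers run the full study end to end, writing tables under
`results/`:

```bash
python analysis/01_simulate_trials.py      # two synthetic studies + ground truth
python analysis/02_longitudinal_response.py  # MMRM LS means, contrasts, effect sizes
python analysis/03_responder_analysis.py   # responder rates, CMH, CDF curves
python analysis/04_mediation_analysis.py   # NDE/NIE report, all mediators
python analysis/05_estimator_validation.py # oracle agreement, bias, additivity
```

A `psafatigue` CLI wraps the same stages (`simulate`, `analyze`, `mediate`,
`report`); try `psafatigue analyze --seed 1 --out results/run1`.

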