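"""MMRM: closed-form equivalences, invariances and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from psafatigue import mmrm, synthetic as syn
from psafatigue._glm import RankDeficientError


def _single_visit_data(seed=0, n=60, effect=3.0, covariate=True):
    rng = np.random.default_rng(seed)
    arm = np.repeat(["Q4W", "PBO"], n // 2)
    base = rng.normal(30, 9, n)
    strat1 = rng.integers(0, 2, n).astype(float)
    strat2 = rng.integers(0, 2, n).astype(float)
    change = (
        effect * (arm == "Q4W")
        - 0.2 * (base - 30)
        + 0.8 * strat1
        + rng.normal(0, 5, n)
    )
    baselines = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "arm": arm,
            "facit_baseline": base,
            "strat_dmard": strat1,
            "strat_second": strat2,
        }
    )
    changes = pd.DataFrame(
        {"patient_id": baselines["patient_id"], "week": 24, "change": change}
    )
    return changes, baselines


def test_single_visit_contrast_equals_ancova():
    """With one visit and complete data the MMRM reduces to covariate-adjusted
    ANCOVA; the treatment contrast must match the OLS coefficient exactly."""
    changes, baselines = _single_visit_data()
    fit = mmrm.fit_mmrm(changes, baselines, mmrm.MmrmConfig(weeks=(24,)))
    est, lo, hi, p = mmrm.ls_mean_contrast(fit, 24, ("Q4W", "PBO"))

    df = changes.merge(baselines, on="patient_id")
    X = sm.add_constant(
        np.column_stack(
            [
                (df["arm"] == "Q4W").astype(float),
                df["facit_baseline"] - df["facit_baseline"].mean(),
                df["strat_dmard"] - df["strat_dmard"].mean(),
                df["strat_second"] - df["strat_second"].mean(),
            ]
        )
    )
    ols = sm.OLS(df["change"], X).fit()
    assert est == pytest.approx(np.asarray(ols.params)[1], abs=1e-8)


def test_balanced_two_arm_no_covariates_is_mean_difference():
    changes, baselines = _single_visit_data(seed=3)
    fit = mmrm.fit_mmrm(
        changes, baselines, mmrm.MmrmConfig(weeks=(24,), covariates=())
    )
    est, *_ = mmrm.ls_mean_contrast(fit, 24, ("Q4W", "PBO"))
    df = changes.merge(baselines, on="patient_id")
    means = df.groupby("arm")["change"].mean()
    assert est == pytest.approx(means["Q4W"] - means["PBO"], abs=1e-8)


def test_contrast_self_zero_and_sign_flip(two_arm_trial):
    changes = syn.change_scores(two_arm_trial.visits)
    fit = mmrm.fit_mmrm(changes, two_arm_trial.baseline)
    est0, lo0, hi0, p0 = mmrm.ls_mean_contrast(fit, 24, ("Q4W", "Q4W"))
    assert est0 == 0.0 and p0 == 1.0
    a = mmrm.ls_mean_contrast(fit, 24, ("Q4W", "PBO"))
    b = mmrm.ls_mean_contrast(fit, 24, ("PBO", "Q4W"))
    assert a[0] == pytest.approx(-b[0])
    assert a[3] == pytest.approx(b[3])


def test_unknown_week_or_arm_rejected(two_arm_trial):
    changes = syn.change_scores(two_arm_trial.visits)
    fit = mmrm.fit_mmrm(changes, two_arm_trial.baseline)
    with pytest.raises(ValueError, match="week"):
        mmrm.ls_mean_contrast(fit, 13, ("Q4W", "PBO"))
    with pytest.raises(ValueError, match="arm"):
        mmrm.ls_mean_contrast(fit, 24, ("Q9W", "PBO"))


def test_matches_from_scratch_gls_on_small_fixture():
    """Given the REML covariance, the fixed effects must equal a from-scratch
    GLS solve on the stacked per-patient design (30-patient fixture)."""
    cfg = syn.TrialConfig(n_per_arm={"Q4W": 15, "PBO": 15}, dropout_hazard=0.0)
    trial = syn.generate_trial(cfg, seed=21)
    changes = syn.change_scores(trial.visits)
    fit = mmrm.fit_mmrm(changes, trial.baseline)

    data = changes.merge(trial.baseline, on="patient_id")
    data = (
        data[data["week"].isin(fit.weeks)]
        .sort_values(["patient_id", "week"])
        .reset_index(drop=True)
    )
    Sinv = np.linalg.inv(fit.sigma)
    A = np.zeros((len(fit.column_names),) * 2)
    b = np.zeros(len(fit.column_names))
    from psafatigue.mmrm import _build_design

    X, names = _build_design(
        data, fit.arms, fit.weeks,
        ("facit_baseline", "strat_dmard", "strat_second"), fit.covariate_means,
    )
    for _, g in data.groupby("patient_id"):
        Xi = X[g.index.to_numpy()]
        yi = g["change"].to_numpy()
        A += Xi.T @ Sinv @ Xi
        b += Xi.T @ Sinv @ yi
    beta_gls = np.linalg.solve(A, b)
    assert fit.beta == pytest.approx(beta_gls, abs=1e-6)


def test_covariance_estimate_is_psd(two_arm_trial):
    changes = syn.change_scores(two_arm_trial.visits)
    fit = mmrm.fit_mmrm(changes, two_arm_trial.baseline)
    eig = np.linalg.eigvalsh(fit.sigma)
    assert np.all(eig >= -1e-10)
    assert fit.sigma == pytest.approx(fit.sigma.T)


def test_row_order_permutation_invariance(two_arm_trial):
    changes = syn.change_scores(two_arm_trial.visits)
    fit1 = mmrm.fit_mmrm(changes, two_arm_trial.baseline)
    rng = np.random.default_rng(4)
    fit2 = mmrm.fit_mmrm(
        changes.sample(frac=1, random_state=7).reset_index(drop=True),
        two_arm_trial.baseline.sample(frac=1, random_state=8).reset_index(drop=True),
    )
    assert fit1.beta == pytest.approx(fit2.beta, abs=1e-10)


def test_singular_design_names_aliased_term():
    changes, baselines = _single_visit_data()
    baselines = baselines.assign(facit_copy=baselines["facit_baseline"])
    with pytest.raises(RankDeficientError, match="facit_copy"):
        mmrm.fit_mmrm(
            changes, baselines,
            mmrm.MmrmConfig(weeks=(24,), covariates=("facit_baseline", "facit_copy")),
        )


def test_compound_symmetry_option_fits(two_arm_trial):
    changes = syn.change_scores(two_arm_trial.visits)
    fit = mmrm.fit_mmrm(
        changes, two_arm_trial.baseline, mmrm.MmrmConfig(covariance="compound_symmetry")
    )
    assert fit.converged
    assert fit.covariance_used == "compound_symmetry"
    off = fit.sigma[np.triu_indices_from(fit.sigma, 1)]
    assert np.allclose(off, off[0])


def test_ls_means_ci_ordering(two_arm_trial):
    changes = syn.change_scores(two_arm_trial.visits)
    fit = mmrm.fit_mmrm(changes, two_arm_trial.baseline)
    t = fit.ls_means()
    assert (t["ci_lower"] <= t["ls_mean_change"]).all()
    assert (t["ls_mean_change"] <= t["ci_upper"]).all()


def test_week24_contrast_recovers_true_total():
    """Parameter recovery at a modest replicate count: the mean week-24
    contrast should sit within sampling error of the generator's true total."""
    reps, ests = 20, []
    cfg = syn.TrialConfig(n_per_arm={"Q4W": 245, "PBO": 246})
    for s in range(reps):
        trial = syn.generate_trial(cfg, seed=5000 + s)
        changes = syn.change_scores(trial.visits)
        fit = mmrm.fit_mmrm(changes, trial.baseline)
        ests.append(mmrm.ls_mean_contrast(fit, 24, ("Q4W", "PBO"))[0])
    truth = trial.truth.true_total
    err = np.mean(ests) - truth
    se = np.std(ests, ddof=1) / np.sqrt(reps)
    assert abs(err) <= max(3 * se, 0.15)
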