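"""Mediation estimators: model fits, decomposition, bootstrap, oracle agreement."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from psafatigue import mediation as med
from psafatigue import synthetic as syn
from psafatigue._glm import LogitSeparationError, logit_fit, ols_fit


def _design_arrays(frame, spec):
    X, names = med._design(frame, spec, with_mediator=False)
    return X, names


class TestInternalEngine:
    """The fast IRLS/OLS engine must agree with statsmodels to high precision."""

    def test_logit_matches_statsmodels(self, acr20_frame):
        spec = med.MediationSpec("ACR20")
        X, _ = _design_arrays(acr20_frame, spec)
        y = acr20_frame["mediator"].to_numpy()
        beta, cov = logit_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert beta == pytest.approx(ref.params, abs=1e-7)
        assert np.diag(cov) == pytest.approx(
            np.diag(np.asarray(ref.cov_params())), rel=1e-4
        )

    def test_ols_matches_statsmodels(self, dcrp_frame):
        spec = med.MediationSpec("dCRP")
        X, _ = _design_arrays(dcrp_frame, spec)
        y = dcrp_frame["outcome"].to_numpy()
        beta, _, _ = ols_fit(X, y)
        ref = sm.OLS(y, X).fit()
        assert beta == pytest.approx(ref.params, abs=1e-8)


class TestMediatorModel:
    def test_null_treatment_effect_recovered(self):
        meds = list(syn.default_mediator_models())
        meds[0] = syn.MediatorModel(
            name="ACR20", kind="binary", intercept=-1.1, arm_effect=0.0,
            coefs=meds[0].coefs,
        )
        zs = []
        for s in range(3):
            trial = syn.generate_trial(
                syn.TrialConfig(n_per_arm={"Q4W": 800, "PBO": 800}, mediators=meds),
                seed=100 + s,
            )
            frame = med.prepare_mediation_data(
                trial.baseline, trial.visits, trial.mediators, "ACR20", "Q4W"
            )
            spec = med.MediationSpec("ACR20")
            X, _ = _design_arrays(frame, spec)
            beta, cov = logit_fit(X, frame["mediator"].to_numpy())
            zs.append(beta[1] / np.sqrt(cov[1, 1]))
        assert all(abs(z) < 3 for z in zs)

    def test_logit_slope_recovery(self):
        meds = list(syn.default_mediator_models())
        meds[0] = syn.MediatorModel(
            name="ACR20", kind="binary", intercept=-1.1, arm_effect=1.0,
            coefs=meds[0].coefs,
        )
        trial = syn.generate_trial(
            syn.TrialConfig(n_per_arm={"Q4W": 2500, "PBO": 2500}, mediators=meds),
            seed=9,
        )
        frame = med.prepare_mediation_data(
            trial.baseline, trial.visits, trial.mediators, "ACR20", "Q4W"
        )
        spec = med.MediationSpec("ACR20")
        X, _ = _design_arrays(frame, spec)
        beta, cov = logit_fit(X, frame["mediator"].to_numpy())
        assert abs(beta[1] - 1.0) <= 3 * np.sqrt(cov[1, 1])

    def test_balanced_covariates_leave_treatment_coef_unchanged(self):
        """With covariates exactly orthogonal to treatment (mirrored design),
        dropping them from a linear mediator model does not move the
        treatment coefficient."""
        rng = np.random.default_rng(3)
        n = 120
        C = rng.normal(0, 1, (n, 2))
        Cfull = np.vstack([C, C])
        t = np.r_[np.ones(n), np.zeros(n)]
        m = 0.8 * t + Cfull @ [0.5, -0.7] + rng.normal(0, 1, 2 * n)
        frame = pd.DataFrame({"treatment": t, "mediator": m, "outcome": 0.0,
                              "c1": Cfull[:, 0], "c2": Cfull[:, 1]})
        with_cov = med.fit_mediator_model(
            frame, med.MediationSpec("M", mediator_kind="continuous",
                                     covariates=("c1", "c2"))
        )
        without = med.fit_mediator_model(
            frame, med.MediationSpec("M", mediator_kind="continuous", covariates=())
        )
        assert with_cov["treatment"] == pytest.approx(without["treatment"], abs=1e-10)

    def test_separation_raises_and_penalty_knob_recovers(self):
        rng = np.random.default_rng(0)
        n = 80
        x = rng.normal(0, 1, n)
        frame = pd.DataFrame(
            {
                "treatment": np.r_[np.ones(n // 2), np.zeros(n // 2)],
                "mediator": (x > 0).astype(float),
                "outcome": rng.normal(0, 1, n),
                "x": x,
            }
        )
        spec = med.MediationSpec("M", mediator_kind="binary", covariates=("x",))
        with pytest.raises(LogitSeparationError):
            med.fit_mediator_model(frame, spec)
        ok = med.fit_mediator_model(
            frame, med.MediationSpec("M", mediator_kind="binary", covariates=("x",),
                                     logit_penalty=1e-2)
        )
        assert np.isfinite(ok).all()


class TestEstimator:
    def test_continuous_mediator_closed_form_truth(self):
        meds = [syn.MediatorModel(name="dCRP", kind="continuous", intercept=0.0,
                                  arm_effect=1.0, noise_sd=1.0)]
        cfg = syn.TrialConfig(
            theta_t=2.0, theta_m=1.0, structural_mediator="dCRP", mediators=meds,
            noise_sd=1.0, n_per_arm={"Q4W": 5000, "PBO": 5000}, dropout_hazard=0.0,
        )
        trial = syn.generate_trial(cfg, seed=17)
        frame = med.prepare_mediation_data(
            trial.baseline, trial.visits, trial.mediators, "dCRP", "Q4W"
        )
        res = med.estimate_nde_nie(frame, med.MediationSpec("dCRP"))
        assert res.nde == pytest.approx(2.0, abs=0.05)
        assert res.nie == pytest.approx(1.0, abs=0.05)

    def test_zero_theta_m_gives_null_nie(self):
        cfg = syn.TrialConfig(theta_m=0.0, n_per_arm={"Q4W": 5000, "PBO": 5000})
        trial = syn.generate_trial(cfg, seed=31)
        frame = med.prepare_mediation_data(
            trial.baseline, trial.visits, trial.mediators, "ACR20", "Q4W"
        )
        res = med.estimate_nde_nie(frame, med.MediationSpec("ACR20"))
        assert abs(res.nie) < 0.2

    @pytest.mark.parametrize("interaction", [False, True])
    def test_binary_estimator_matches_counterfactual_oracle(
        self, acr20_frame, interaction
    ):
        spec = med.MediationSpec("ACR20", interaction=interaction)
        res = med.estimate_nde_nie(acr20_frame, spec)
        orc = med.counterfactual_oracle(acr20_frame, spec, n_draws=400_000, seed=3)
        assert abs(res.nde - orc["nde"]) <= 2 * orc["nde_mc_se"] + 1e-6
        assert abs(res.nie - orc["nie"]) <= 2 * orc["nie_mc_se"] + 1e-6

    @pytest.mark.parametrize("interaction", [False, True])
    def test_continuous_estimator_matches_counterfactual_oracle(
        self, dcrp_frame, interaction
    ):
        spec = med.MediationSpec("dCRP", interaction=interaction)
        res = med.estimate_nde_nie(dcrp_frame, spec)
        orc = med.counterfactual_oracle(dcrp_frame, spec, n_draws=400_000, seed=4)
        assert abs(res.nde - orc["nde"]) <= 2 * orc["nde_mc_se"] + 1e-6
        assert abs(res.nie - orc["nie"]) <= 2 * orc["nie_mc_se"] + 1e-6

    def test_additivity_is_exact_for_linear_mediator_model(self, dcrp_frame):
        res = med.estimate_nde_nie(dcrp_frame, med.MediationSpec("dCRP"))
        assert res.nde + res.nie == pytest.approx(res.total_regression, abs=1e-9)

    def test_input_validation(self, acr20_frame):
        with pytest.raises(ValueError, match="missing columns"):
            med.estimate_nde_nie(
                acr20_frame.drop(columns=["bmi"]), med.MediationSpec("ACR20")
            )
        bad = acr20_frame.copy()
        bad.loc[0, "outcome"] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            med.estimate_nde_nie(bad, med.MediationSpec("ACR20"))
        one_arm = acr20_frame[acr20_frame["treatment"] == 1]
        with pytest.raises(ValueError, match="binary"):
            med.estimate_nde_nie(one_arm, med.MediationSpec("ACR20"))


class TestProportionMediated:
    @pytest.mark.parametrize(
        "nde, nie, pct_dir, pct_ind",
        [
            (2.34, 0.74, 76.0, 24.0),   # dichotomous-mediator worked example
            (3.19, 0.42, 88.4, 11.6),   # continuous-mediator worked example
            (5.0, 0.0, 100.0, 0.0),
        ],
    )
    def test_worked_examples(self, nde, nie, pct_dir, pct_ind):
        d, i = med.proportion_mediated(nde, nie)
        assert round(d, 1) == pct_dir
        assert round(i, 1) == pct_ind

    def test_sums_to_hundred(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            nde, nie = rng.normal(2, 1), rng.normal(1, 0.5)
            d, i = med.proportion_mediated(nde, nie)
            assert d + i == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_flagged(self):
        with pytest.raises(med.ZeroTotalEffectError):
            med.proportion_mediated(1.0, -1.0)

    def test_opposite_signs_warn(self):
        with pytest.warns(UserWarning, match="opposite signs"):
            d, i = med.proportion_mediated(3.0, -1.0)
        assert d > 100.0 and i < 0.0


class TestBootstrap:
    def test_same_seed_identical_cis(self, acr20_frame):
        spec = med.MediationSpec("ACR20", bootstrap_reps=100, seed=42)
        a = med.bootstrap_mediation(acr20_frame, spec)
        b = med.bootstrap_mediation(acr20_frame, spec)
        assert a.nde_ci == b.nde_ci and a.nie_ci == b.nie_ci

    def test_point_estimate_is_full_data_estimate(self, acr20_frame):
        spec = med.MediationSpec("ACR20", bootstrap_reps=50, seed=1)
        boot = med.bootstrap_mediation(acr20_frame, spec)
        point = med.estimate_nde_nie(acr20_frame, spec)
        assert boot.nde == point.nde and boot.nie == point.nie

    def test_noiseless_outcome_fixture_degenerate_bootstrap(self):
        """With a noiseless outcome the outcome model fits every resample
        exactly, so the NDE bootstrap distribution is a point mass (CI width
        exactly 0). The mediator equation must retain residual variation:
        if it were also noiseless the mediator would be an exact linear
        function of the outcome design and the fit would be singular, so a
        fully noiseless fixture cannot exist for this estimator."""
        rng = np.random.default_rng(2)
        n = 100
        c1 = rng.normal(0, 1, 2 * n)
        t = np.r_[np.ones(n), np.zeros(n)]
        m = 1.5 * t + 0.5 * c1 + rng.normal(0, 0.7, 2 * n)
        y = 2.0 * t + 1.0 * m + 0.3 * c1    # no outcome noise
        frame = pd.DataFrame({"treatment": t, "mediator": m, "outcome": y, "c1": c1})
        spec = med.MediationSpec(
            "M", mediator_kind="continuous", covariates=("c1",),
            bootstrap_reps=50, seed=3,
        )
        res = med.bootstrap_mediation(frame, spec)
        assert res.nde_ci[1] - res.nde_ci[0] == pytest.approx(0.0, abs=1e-8)
        assert res.nde == pytest.approx(2.0, abs=1e-8)
        assert res.nie == pytest.approx(1.5, abs=0.3)

    def test_degenerate_resamples_are_redrawn(self):
        rng = np.random.default_rng(4)
        n1, n0 = 60, 12
        t = np.r_[np.ones(n1), np.zeros(n0)]
        m = np.r_[rng.integers(0, 2, n1).astype(float), np.zeros(n0)]
        m[n1] = 1.0  # single control responder -> degenerate resamples likely
        y = 1.0 * t + 0.5 * m + rng.normal(0, 1, n1 + n0)
        frame = pd.DataFrame({"treatment": t, "mediator": m, "outcome": y})
        spec = med.MediationSpec(
            "M", mediator_kind="binary", covariates=(), bootstrap_reps=200, seed=5
        )
        res = med.bootstrap_mediation(frame, spec)
        assert res.diagnostics["redraws"] > 0
        assert np.isfinite(res.nie_ci).all()


def test_prepare_mediation_data_complete_case(two_arm_trial):
    t = two_arm_trial
    frame = med.prepare_mediation_data(t.baseline, t.visits, t.mediators, "ACR20", "Q4W")
    assert not frame.isna().any().any()
    assert set(np.unique(frame["treatment"])) == {0.0, 1.0}
    with pytest.raises(ValueError, match="not present"):
        med.prepare_mediation_data(t.baseline, t.visits, t.mediators, "NOPE", "Q4W")
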