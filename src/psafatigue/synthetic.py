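"""Synthetic two-study, three-arm PsA trial generator with recorded ground truth.

Emulates the data structure of a placebo-controlled psoriatic-arthritis
trial programme evaluating fatigue: two studies (``D1``, ``D2``) with arms
``Q4W``, ``Q8W`` (active) and ``PBO``; baseline covariates calibrated to the
published per-study marginals; binary clinical-response mediators (ACR20,
MDA) drawn from a logistic model in arm and covariates; a continuous
mediator (change in CRP) drawn from a linear model; and FACIT-Fatigue
change scores following a linear structural model

    change_24 = mu0 + theta_t * 1[active] + theta_m * M + gamma' C + eps

whose direct (``theta_t``) and mediator-transmitted (``theta_m * E[M(1)-M(0)]``)
components are recorded in a :class:`SimulationTruth` for recovery testing.

FACIT-Fatigue is a 0-52 scale (higher = less fatigue). Baseline scores are
truncated to the instrument range; post-baseline scores follow the linear
structural model exactly and are deliberately not censored at the scale
bounds (see the note in :func:`generate_trial`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ARMS = ("Q4W", "Q8W", "PBO")
ACTIVE_ARMS = ("Q4W", "Q8W")
VISIT_WEEKS = (0, 4, 8, 16, 24, 32, 40, 48, 52)
LANDMARK_WEEK = 24
FACIT_MAX = 52.0

MEDIATOR_KINDS = {"ACR20": "binary", "MDA": "binary", "dCRP": "continuous"}

# Covariates entering the mediator and outcome linear predictors (centered
# at the study's theoretical marginal mean so intercepts are interpretable
# as reference rates/levels).
ADJUSTMENT_COVARIATES = (
    "age", "sex", "bmi", "facit_baseline", "crp_baseline", "psa_duration",
    "pga", "ptga_arthritis", "haqdi", "pain", "sjc", "tjc",
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Mu/sigma of a lognormal with the requested mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class CovariateModel:
    """Per-study marginal distributions for baseline characteristics.

    Continuous covariates are normal or lognormal, truncated/clipped to the
    instrument range; counts are rounded. Covariates are drawn independently:
    the published tables report marginals only, and independence keeps the
    structural ground truth transparent.
    """

    age_mean: float
    age_sd: float
    male_p: float
    bmi_mean: float
    bmi_sd: float
    duration_mean: float
    duration_sd: float
    facit_mean: float
    facit_sd: float
    sjc_mean: float
    sjc_sd: float
    tjc_mean: float
    tjc_sd: float
    crp_median: float
    crp_log_sd: float
    pasi_mean: float
    pasi_sd: float
    haqdi_mean: float
    haqdi_sd: float
    pga_mean: float
    pga_sd: float
    ptga_mean: float
    ptga_sd: float
    pain_mean: float
    pain_sd: float
    enthesitis_p: float
    lei_mean: float
    lei_sd: float
    dmard_p: float
    tnfi_p: float | None  # None => second stratification factor is CRP > 2.0

    def theoretical_means(self) -> dict[str, float]:
        """Approximate marginal means used to center linear predictors."""
        crp_mean = self.crp_median * float(np.exp(self.crp_log_sd**2 / 2.0))
        return {
            "age": self.age_mean,
            "sex": self.male_p,
            "bmi": self.bmi_mean,
            "facit_baseline": self.facit_mean,
            "crp_baseline": crp_mean,
            "psa_duration": self.duration_mean,
            "pga": self.pga_mean,
            "ptga_arthritis": self.ptga_mean,
            "haqdi": self.haqdi_mean,
            "pain": self.pain_mean,
            "sjc": self.sjc_mean,
            "tjc": self.tjc_mean,
            "pasi": self.pasi_mean,
        }

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        dmu, dsg = _lognormal_params(self.duration_mean, self.duration_sd)
        smu, ssg = _lognormal_params(self.sjc_mean, self.sjc_sd)
        tmu, tsg = _lognormal_params(self.tjc_mean, self.tjc_sd)
        pmu, psg = _lognormal_params(self.pasi_mean, self.pasi_sd)
        has_enth = rng.random(n) < self.enthesitis_p
        lei = np.where(
            has_enth,
            np.clip(np.rint(rng.normal(self.lei_mean, self.lei_sd, n)), 1, 6),
            0.0,
        )
        out = pd.DataFrame(
            {
                "age": np.clip(rng.normal(self.age_mean, self.age_sd, n), 18, 90),
                "sex": (rng.random(n) < self.male_p).astype(float),
                "bmi": np.clip(rng.normal(self.bmi_mean, self.bmi_sd, n), 15, 60),
                "psa_duration": np.clip(rng.lognormal(dmu, dsg, n), 0.05, 50),
                "facit_baseline": np.clip(
                    rng.normal(self.facit_mean, self.facit_sd, n), 0, FACIT_MAX
                ),
                "crp_baseline": rng.lognormal(np.log(self.crp_median), self.crp_log_sd, n),
                "pga": np.clip(rng.normal(self.pga_mean, self.pga_sd, n), 0, 10),
                "ptga_arthritis": np.clip(rng.normal(self.ptga_mean, self.ptga_sd, n), 0, 10),
                "pain": np.clip(rng.normal(self.pain_mean, self.pain_sd, n), 0, 10),
                "haqdi": np.clip(rng.normal(self.haqdi_mean, self.haqdi_sd, n), 0, 3),
                "sjc": np.clip(np.rint(rng.lognormal(smu, ssg, n)), 0, 66),
                "tjc": np.clip(np.rint(rng.lognormal(tmu, tsg, n)), 0, 68),
                "pasi": np.clip(rng.lognormal(pmu, psg, n), 0, 72),
                "tender_entheseal_points": lei,
                "strat_dmard": (rng.random(n) < self.dmard_p).astype(float),
            }
        )
        if self.tnfi_p is None:
            out["strat_second"] = (out["crp_baseline"] > 2.0).astype(float)
        else:
            out["strat_second"] = (rng.random(n) < self.tnfi_p).astype(float)
        return out


# Calibrated to the published baseline tables (arm-pooled means/SDs; CRP from
# the reported median/IQR of a lognormal).
STUDY_COVARIATES: dict[str, CovariateModel] = {
    "D1": CovariateModel(
        age_mean=48.3, age_sd=11.7, male_p=0.512,
        bmi_mean=29.8, bmi_sd=5.9,
        duration_mean=6.7, duration_sd=6.6,
        facit_mean=30.4, facit_sd=10.4,
        sjc_mean=9.9, sjc_sd=7.4, tjc_mean=19.2, tjc_sd=14.0,
        crp_median=0.70, crp_log_sd=1.20,
        pasi_mean=8.5, pasi_sd=9.6,
        haqdi_mean=1.13, haqdi_sd=0.6,
        pga_mean=6.2, pga_sd=1.7, ptga_mean=6.2, ptga_sd=2.1,
        pain_mean=5.9, pain_sd=2.1,
        enthesitis_p=0.58, lei_mean=2.8, lei_sd=1.6,
        dmard_p=0.65, tnfi_p=0.31,
    ),
    "D2": CovariateModel(
        age_mean=45.7, age_sd=12.0, male_p=0.525,
        bmi_mean=28.9, bmi_sd=6.2,
        duration_mean=5.5, duration_sd=5.7,
        facit_mean=29.7, facit_sd=9.7,
        sjc_mean=12.3, sjc_sd=7.2, tjc_mean=21.3, tjc_sd=12.8,
        crp_median=1.20, crp_log_sd=1.05,
        pasi_mean=9.9, pasi_sd=11.1,
        haqdi_mean=1.27, haqdi_sd=0.6,
        pga_mean=6.6, pga_sd=1.5, ptga_mean=6.5, ptga_sd=1.9,
        pain_mean=6.3, pain_sd=1.9,
        enthesitis_p=0.68, lei_mean=2.8, lei_sd=1.6,
        dmard_p=0.65, tnfi_p=None,
    ),
}


@dataclass(frozen=True)
class MediatorModel:
    """Structural model for one mediator.

    Binary: logit P(M=1) = intercept + arm_effect*1[active] + coefs' (C - E[C]).
    Continuous: M = intercept + arm_effect*1[active] + coefs' (C - E[C]) + N(0, noise_sd).
    """

    name: str
    kind: str  # "binary" | "continuous"
    intercept: float
    arm_effect: float
    coefs: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def linear_predictor(
        self, covariates: pd.DataFrame, active: np.ndarray, means: Mapping[str, float]
    ) -> np.ndarray:
        eta = np.full(len(covariates), self.intercept) + self.arm_effect * active
        for name, coef in self.coefs.items():
            eta = eta + coef * (covariates[name].to_numpy() - means[name])
        return eta


@dataclass(frozen=True)
class TrialConfig:
    """Generator settings; defaults are the package's reference conditions."""

    study: str = "D2"
    n_per_arm: Mapping[str, int] = field(
        default_factory=lambda: {"Q4W": 245, "Q8W": 248, "PBO": 246}
    )
    seed: int = 0
    # Outcome structural model (FACIT change at the landmark week).
    theta_t: float = 2.5            # natural direct effect, FACIT points
    theta_m: float = 3.2            # outcome shift per unit of the structural mediator
    structural_mediator: str = "ACR20"
    mu0: float = 2.0                # secular improvement shared by all arms
    gamma: Mapping[str, float] = field(
        default_factory=lambda: {"facit_baseline": -0.25, "haqdi": -0.8, "age": -0.02}
    )
    noise_sd: float = 7.5           # total SD of eps at the landmark week
    within_subject_corr: float = 0.5  # share of noise variance from the subject intercept
    # Mediator models; None -> defaults for the study.
    mediators: Sequence[MediatorModel] | None = None
    dropout_hazard: float = 0.02    # per-visit discontinuation probability (MAR)
    failure_prob: float = 0.0       # per-patient treatment-failure probability
    truth_mc_draws: int = 200_000   # covariate draws for the binary-mediator truth

    def resolved_mediators(self) -> tuple[MediatorModel, ...]:
        if self.mediators is not None:
            return tuple(self.mediators)
        return default_mediator_models()


def default_mediator_models() -> tuple[MediatorModel, ...]:
    """Reference mediator models: active-arm response rates near the trial's."""
    return (
        MediatorModel(
            name="ACR20", kind="binary", intercept=-1.10, arm_effect=1.55,
            coefs={"facit_baseline": 0.015, "bmi": -0.03, "psa_duration": -0.02},
        ),
        MediatorModel(
            name="MDA", kind="binary", intercept=-2.59, arm_effect=1.35,
            coefs={"haqdi": -0.40, "pasi": -0.02},
        ),
        MediatorModel(
            name="dCRP", kind="continuous", intercept=0.05, arm_effect=-0.90,
            coefs={"crp_baseline": -0.25}, noise_sd=1.2,
        ),
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth effect decomposition under the generator's structural model."""

    mediator_name: str
    true_nde: float
    true_nie: float
    true_total: float
    generator_params: dict

    def __post_init__(self):
        if not np.isclose(self.true_total, self.true_nde + self.true_nie):
            raise ValueError("true_total must equal true_nde + true_nie")


@dataclass(frozen=True)
class TrialData:
    """One simulated study: baseline, visit, mediator and component tables."""

    baseline: pd.DataFrame
    visits: pd.DataFrame
    mediators: pd.DataFrame
    components: pd.DataFrame
    truth: SimulationTruth


def _validate(config: TrialConfig) -> None:
    if config.study not in STUDY_COVARIATES:
        raise ValueError(f"unknown study {config.study!r}; expected one of {sorted(STUDY_COVARIATES)}")
    for arm, n in config.n_per_arm.items():
        if arm not in ARMS:
            raise ValueError(f"unknown arm label {arm!r}; expected one of {ARMS}")
        if n < 2:
            raise ValueError(f"n per arm must be >= 2, got {n} for arm {arm!r}")
    if config.noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    med_names = {m.name for m in config.resolved_mediators()}
    if config.structural_mediator not in med_names:
        raise ValueError(
            f"structural mediator {config.structural_mediator!r} not among {sorted(med_names)}"
        )
    for m in config.resolved_mediators():
        if not np.all(np.isfinite([m.intercept, m.arm_effect, *m.coefs.values()])):
            raise ValueError(f"non-finite coefficient in mediator model {m.name!r}")
        if m.noise_sd < 0:
            raise ValueError(f"negative noise SD in mediator model {m.name!r}")


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_TRUTH_CACHE: dict[tuple, float] = {}


def _mediator_truth(config: TrialConfig) -> float:
    """E[M(active) - M(placebo)] over the covariate distribution.

    Closed form for a continuous mediator; Monte-Carlo over a fresh covariate
    sample for a binary one (the logistic marginalization has no closed
    form). This is a population quantity, so the Monte-Carlo stream is seeded
    by a fixed internal constant (not the data seed) and cached per model.
    """
    model = next(
        m for m in config.resolved_mediators() if m.name == config.structural_mediator
    )
    if model.kind == "continuous":
        return model.arm_effect
    key = (
        config.study, model.name, model.intercept, model.arm_effect,
        tuple(sorted(model.coefs.items())), config.truth_mc_draws,
    )
    if key not in _TRUTH_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([777, config.truth_mc_draws]))
        cov_model = STUDY_COVARIATES[config.study]
        draws = cov_model.draw(config.truth_mc_draws, rng)
        means = cov_model.theoretical_means()
        eta0 = model.linear_predictor(draws, np.zeros(len(draws)), means)
        _TRUTH_CACHE[key] = float(
            np.mean(_invlogit(eta0 + model.arm_effect) - _invlogit(eta0))
        )
    return _TRUTH_CACHE[key]


def _time_profile(weeks: np.ndarray) -> np.ndarray:
    """Fractional attainment of the landmark-week effect: linear ramp, then plateau."""
    return np.minimum(weeks / LANDMARK_WEEK, 1.0)


def generate_trial(config: TrialConfig | None = None, **overrides) -> TrialData:
    """Simulate one study; deterministic for a fixed config (incl. seed).

    Returns patient baseline, long-format visit, long-format mediator and
    ACR20/MDA component tables plus the structural-model :class:`SimulationTruth`.
    """
    if config is None:
        config = TrialConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    _validate(config)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2024]))
    cov_model = STUDY_COVARIATES[config.study]
    means = cov_model.theoretical_means()

    arms = np.concatenate([np.repeat(a, config.n_per_arm.get(a, 0)) for a in ARMS])
    n = len(arms)
    baseline = cov_model.draw(n, rng)
    baseline.insert(0, "patient_id", [f"{config.study}-{i:05d}" for i in range(n)])
    baseline.insert(1, "study", config.study)
    baseline.insert(2, "arm", arms)
    active = np.isin(arms, ACTIVE_ARMS).astype(float)

    # Mediators at the landmark week.
    med_frames = []
    med_values: dict[str, np.ndarray] = {}
    for model in config.resolved_mediators():
        eta = model.linear_predictor(baseline, active, means)
        if model.kind == "binary":
            value = (rng.random(n) < _invlogit(eta)).astype(float)
        else:
            value = eta + rng.normal(0.0, model.noise_sd, n)
        med_values[model.name] = value
        med_frames.append(
            pd.DataFrame(
                {
                    "patient_id": baseline["patient_id"],
                    "mediator": model.name,
                    "kind": model.kind,
                    "value": value,
                }
            )
        )
    mediators = pd.concat(med_frames, ignore_index=True)

    # Landmark FACIT change under the structural model.
    M = med_values[config.structural_mediator]
    systematic = config.mu0 + config.theta_t * active + config.theta_m * M
    for name, coef in config.gamma.items():
        systematic = systematic + coef * (baseline[name].to_numpy() - means[name])

    sd_b = config.noise_sd * np.sqrt(config.within_subject_corr)
    sd_e = config.noise_sd * np.sqrt(1.0 - config.within_subject_corr)
    b_i = rng.normal(0.0, sd_b, n)

    weeks = np.array(VISIT_WEEKS[1:], dtype=float)
    profile = _time_profile(weeks)
    change = (
        profile[None, :] * systematic[:, None]
        + b_i[:, None]
        + rng.normal(0.0, sd_e, (n, len(weeks)))
    )
    # Post-baseline scores are NOT clipped to the 0-52 instrument range: the
    # recorded ground truth (and every recovery test built on it) relies on
    # the landmark change following the linear structural model exactly, and
    # censoring at the scale bounds would break that identity. Baseline
    # scores are truncated to the instrument range; simulated follow-up
    # scores exceed 52 for a few percent of well-responding patients, a
    # documented idealisation relative to the real instrument.
    base_scores = baseline["facit_baseline"].to_numpy()
    scores = base_scores[:, None] + change

    # Monotone MAR dropout: once missing, missing thereafter.
    drop = rng.random((n, len(weeks))) < config.dropout_hazard
    dropped = np.cumsum(drop, axis=1) > 0
    scores = np.where(dropped, np.nan, scores)

    visits = pd.DataFrame(
        {
            "patient_id": np.repeat(baseline["patient_id"].to_numpy(), len(VISIT_WEEKS)),
            "week": np.tile(VISIT_WEEKS, n),
            "facit_score": np.column_stack([base_scores, scores]).ravel(),
            "failed": 0,
        }
    )

    if config.failure_prob > 0:
        fail = rng.random(n) < config.failure_prob
        fail_weeks = rng.choice(VISIT_WEEKS[1:5], size=n)  # failures arise on-study, pre-landmark
        failure_events = {
            pid: int(w)
            for pid, w, f in zip(baseline["patient_id"], fail_weeks, fail)
            if f
        }
        visits = apply_treatment_failure(visits, failure_events)

    # component improvements track the clinical-responder draw when a binary
    # responder mediator is present; otherwise only the arm effect applies
    binary_meds = [m for m in config.resolved_mediators() if m.kind == "binary"]
    responder = med_values[binary_meds[0].name] if binary_meds else np.zeros(n)
    components = _component_panel(baseline, active, responder, rng)

    delta_m = _mediator_truth(config)
    nie = config.theta_m * delta_m
    truth = SimulationTruth(
        mediator_name=config.structural_mediator,
        true_nde=config.theta_t,
        true_nie=nie,
        true_total=config.theta_t + nie,
        generator_params={
            "theta_t": config.theta_t,
            "theta_m": config.theta_m,
            "mediator_arm_contrast": delta_m,
            "mu0": config.mu0,
            "gamma": dict(config.gamma),
            "noise_sd": config.noise_sd,
            "study": config.study,
            "seed": config.seed,
        },
    )
    return TrialData(baseline, visits, mediators, components, truth)


def _component_panel(
    baseline: pd.DataFrame, active: np.ndarray, responder: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Baseline and landmark ACR20/MDA component values.

    Landmark values shrink each baseline component by a random improvement
    fraction whose mean is larger in active arms and in patients drawn as
    clinical responders, giving component-derived endpoints a realistic
    association with arm without entering the outcome model.
    """
    comp_cols = [
        "tjc", "sjc", "pain", "ptga_arthritis", "pga", "haqdi",
        "crp_baseline", "pasi", "tender_entheseal_points",
    ]
    n = len(baseline)
    base = baseline[["patient_id", *comp_cols]].rename(columns={"crp_baseline": "crp"})
    base = base.copy()
    base.insert(1, "timepoint", "baseline")

    land = {"patient_id": baseline["patient_id"], "timepoint": "landmark"}
    mean_f = 0.10 + 0.20 * active + 0.30 * responder
    for col in comp_cols:
        f = np.clip(rng.normal(mean_f, 0.25, n), -0.5, 1.0)
        new = baseline[col].to_numpy() * (1.0 - f)
        if col in ("tjc", "sjc", "tender_entheseal_points"):
            new = np.rint(np.maximum(new, 0.0))
        else:
            new = np.maximum(new, 0.0)
        land[col.replace("crp_baseline", "crp")] = new
    landmark = pd.DataFrame(land)
    return pd.concat([base, landmark], ignore_index=True)


def apply_treatment_failure(
    visits: pd.DataFrame, failure_events: Mapping[str, int]
) -> pd.DataFrame:
    """Zero out the change from baseline at and after each patient's failure week.

    The score is reset to the patient's week-0 value (change = 0) from the
    failure week onwards and the ``failed`` flag set; earlier visits are
    untouched. Returns a new frame; the input is not modified.
    """
    for week in failure_events.values():
        if week not in VISIT_WEEKS:
            raise ValueError(f"failure week {week} is not a scheduled visit week {VISIT_WEEKS}")
    out = visits.copy()
    base_by_pid = (
        out.loc[out["week"] == 0].set_index("patient_id")["facit_score"].to_dict()
    )
    pid = out["patient_id"].to_numpy()
    week = out["week"].to_numpy()
    fail_week = np.array([failure_events.get(p, np.inf) for p in pid])
    mask = (week >= fail_week) & (week > 0)
    out.loc[mask, "facit_score"] = [base_by_pid[p] for p in pid[mask]]
    out.loc[week >= fail_week, "failed"] = 1
    return out


def change_scores(visits: pd.DataFrame) -> pd.DataFrame:
    """Long-format change-from-baseline table (post-baseline weeks only)."""
    base = visits.loc[visits["week"] == 0, ["patient_id", "facit_score"]].rename(
        columns={"facit_score": "facit_baseline_score"}
    )
    post = visits.loc[visits["week"] > 0].merge(base, on="patient_id", how="left")
    post["change"] = post["facit_score"] - post["facit_baseline_score"]
    return post[["patient_id", "week", "change", "failed"]]
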