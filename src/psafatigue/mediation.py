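"""Natural direct / indirect effect decomposition with bootstrap CIs.

The treatment effect on FACIT-Fatigue change at the landmark visit is
decomposed, for one mediator at a time, into

* NDE — the natural direct effect, the part of the effect not transmitted
  through the mediator, and
* NIE — the natural indirect effect, the part transmitted through the
  treatment's effect on the mediator,

in the counterfactual framework. Two regressions are fitted: a mediator
model (logistic for binary mediators such as ACR20/MDA achievement, linear
for continuous ones such as change in CRP) and a linear outcome model
``Y ~ treatment + mediator + covariates``. Without exposure-mediator
interaction the estimators reduce to the familiar product forms:

* NDE = outcome-model treatment coefficient;
* NIE (continuous M) = (outcome M-coefficient) x (mediator-model treatment
  coefficient);
* NIE (binary M) = (outcome M-coefficient) x mean over analysed patients of
  ``invlogit(eta | T=1) - invlogit(eta | T=0)``.

With the interaction flag on, counterfactual-standardisation formulas
generalise these (NDE averages over each patient's mediator distribution
under control). Confidence intervals come from a nonparametric percentile
bootstrap with patient-level resampling stratified by arm. A Monte-Carlo
counterfactual simulator is provided as an independent estimator of the
same quantities from the fitted models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._glm import LogitSeparationError, logit_fit, ols_fit

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    "age", "sex", "bmi", "facit_baseline", "crp_baseline", "psa_duration",
    "pga", "ptga_arthritis", "haqdi", "pain", "sjc", "tjc",
)
MEDIATOR_KINDS = {"ACR20": "binary", "MDA": "binary", "dCRP": "continuous"}


class ZeroTotalEffectError(ZeroDivisionError):
    """Total effect is numerically zero; percent mediated is undefined."""


@dataclass(frozen=True)
class MediationSpec:
    mediator_name: str = "ACR20"
    mediator_kind: str | None = None       # inferred from name when None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    interaction: bool = False
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    logit_penalty: float = 0.0             # ridge fallback knob for separation

    @property
    def kind(self) -> str:
        if self.mediator_kind is not None:
            return self.mediator_kind
        try:
            return MEDIATOR_KINDS[self.mediator_name]
        except KeyError:
            raise ValueError(
                f"unknown mediator {self.mediator_name!r}: give mediator_kind explicitly"
            ) from None

    def __post_init__(self):
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.mediator_kind is not None and self.mediator_kind not in ("binary", "continuous"):
            raise ValueError("mediator_kind must be 'binary' or 'continuous'")


@dataclass
class MediationResult:
    mediator_name: str
    nde: float
    nie: float
    total: float
    total_regression: float                 # T coefficient of Y ~ treatment + covariates
    pct_direct: float | None
    pct_indirect: float | None
    nde_ci: tuple[float, float] | None = None
    nie_ci: tuple[float, float] | None = None
    total_ci: tuple[float, float] | None = None
    mediator_coefs: pd.Series | None = None
    outcome_coefs: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)


def proportion_mediated(nde: float, nie: float) -> tuple[float, float]:
    """(pct_direct, pct_indirect) = 100*(nde, nie)/(nde+nie), unrounded.

    Raises :class:`ZeroTotalEffectError` when the total effect is numerically
    zero. When NDE and NIE have opposite signs the ratios are still reported
    (they then fall outside [0, 100]) with a warning.
    """
    total = nde + nie
    if abs(total) < 1e-12:
        raise ZeroTotalEffectError("total effect is numerically zero")
    pct_direct = 100.0 * nde / total
    pct_indirect = 100.0 * nie / total
    if not (0.0 <= pct_indirect <= 100.0):
        warnings.warn(
            "NDE and NIE have opposite signs; percent mediated falls outside [0, 100]",
            stacklevel=2,
        )
    return pct_direct, pct_indirect


def _design(data: pd.DataFrame, spec: MediationSpec, with_mediator: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data)), data["treatment"].to_numpy(float)]
    names = ["intercept", "treatment"]
    if with_mediator:
        m = data["mediator"].to_numpy(float)
        cols.append(m)
        names.append("mediator")
        if spec.interaction:
            cols.append(data["treatment"].to_numpy(float) * m)
            names.append("treatment:mediator")
    for c in spec.covariates:
        cols.append(data[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names


def fit_mediator_model(data: pd.DataFrame, spec: MediationSpec) -> pd.Series:
    """ML fit of the mediator model M ~ treatment + covariates.

    Logistic for binary mediators, OLS for continuous. Complete-case; raises
    on rank deficiency. On separation of a logistic fit, a ridge-penalised
    refit is attempted when ``spec.logit_penalty`` > 0, otherwise the error
    propagates.
    """
    X, names = _design(data, spec, with_mediator=False)
    m = data["mediator"].to_numpy(float)
    if spec.kind == "binary":
        try:
            beta, _ = logit_fit(X, m, check_rank=True)
        except LogitSeparationError:
            if spec.logit_penalty <= 0:
                raise
            logger.warning(
                "separation in %s mediator model; refitting with ridge penalty %g",
                spec.mediator_name, spec.logit_penalty,
            )
            beta = _penalized_logit(X, m, spec.logit_penalty)
    else:
        beta, _, _ = ols_fit(X, m, check_rank=True)
    return pd.Series(beta, index=names)


def _penalized_logit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    n, p = X.shape
    beta = np.zeros(p)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(200):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu) - lam * np.r_[0.0, beta[1:]]
        H = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-9:
            break
    return beta


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _point_estimates(
    data: pd.DataFrame, spec: MediationSpec,
) -> tuple[float, float, float, pd.Series, pd.Series]:
    """(nde, nie, total_regression, mediator_coefs, outcome_coefs)."""
    med = fit_mediator_model(data, spec)
    Xo, out_names = _design(data, spec, with_mediator=True)
    y = data["outcome"].to_numpy(float)
    bo, _, _ = ols_fit(Xo, y)
    out = pd.Series(bo, index=out_names)

    Xt, _ = _design(data, spec, with_mediator=False)
    bt_total, _, _ = ols_fit(Xt, y)
    total_reg = float(bt_total[1])

    Xm, med_names = _design(data, spec, with_mediator=False)
    b_t = float(out["treatment"])
    b_m = float(out["mediator"])
    b_i = float(out.get("treatment:mediator", 0.0))

    if spec.kind == "binary":
        # linear predictor with treatment forced to 0 / 1 for every patient
        base = Xm @ med.to_numpy() - med["treatment"] * data["treatment"].to_numpy(float)
        p0 = _invlogit(base)
        p1 = _invlogit(base + med["treatment"])
        nde = b_t + b_i * float(np.mean(p0))
        nie = (b_m + b_i) * float(np.mean(p1 - p0))
    else:
        base = Xm @ med.to_numpy() - med["treatment"] * data["treatment"].to_numpy(float)
        m0_mean = float(np.mean(base))
        nde = b_t + b_i * m0_mean
        nie = (b_m + b_i) * float(med["treatment"])
    return nde, nie, total_reg, med, out


def estimate_nde_nie(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Point estimates of NDE, NIE, total effect and percent mediated.

    ``data`` is complete-case with columns ``treatment`` (0/1), ``mediator``,
    ``outcome`` and the spec's covariates.
    """
    _check_input(data, spec)
    nde, nie, total_reg, med, out = _point_estimates(data, spec)
    total = nde + nie
    try:
        pct_direct, pct_indirect = proportion_mediated(nde, nie)
    except ZeroTotalEffectError:
        logger.warning("total effect numerically zero; percent mediated undefined")
        pct_direct = pct_indirect = None
    return MediationResult(
        mediator_name=spec.mediator_name,
        nde=nde, nie=nie, total=total, total_regression=total_reg,
        pct_direct=pct_direct, pct_indirect=pct_indirect,
        mediator_coefs=med, outcome_coefs=out,
        diagnostics={"n": int(len(data)), "kind": spec.kind, "interaction": spec.interaction},
    )


def _check_input(data: pd.DataFrame, spec: MediationSpec) -> None:
    needed = {"treatment", "mediator", "outcome", *spec.covariates}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"mediation data missing columns: {sorted(missing)}")
    if data[sorted(needed)].isna().any().any():
        raise ValueError("mediation data must be complete-case; drop missing rows first")
    t = set(np.unique(data["treatment"]))
    if not t <= {0, 1} or len(t) != 2:
        raise ValueError("treatment must be binary 0/1 with both levels present")


def bootstrap_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Full-data point estimates with percentile bootstrap CIs.

    Patients are resampled with replacement within arm (stratified, so the
    allocation ratio is preserved). Resamples with a degenerate binary
    mediator (all 0 or all 1) are redrawn and counted. Deterministic for a
    fixed spec seed.
    """
    result = estimate_nde_nie(data, spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 515]))
    t = data["treatment"].to_numpy(float)
    idx_treated = np.nonzero(t == 1)[0]
    idx_control = np.nonzero(t == 0)[0]

    fast = _FastEstimator(data, spec)
    est = np.empty((spec.bootstrap_reps, 2))
    redraws = 0
    for b in range(spec.bootstrap_reps):
        for _attempt in range(100):
            idx = np.concatenate(
                [
                    rng.choice(idx_treated, idx_treated.size, replace=True),
                    rng.choice(idx_control, idx_control.size, replace=True),
                ]
            )
            try:
                est[b] = fast.nde_nie(idx)
                break
            except (_DegenerateResample, LogitSeparationError, np.linalg.LinAlgError):
                redraws += 1
        else:
            raise RuntimeError("bootstrap resample failed 100 consecutive redraws")
    if redraws:
        logger.info("bootstrap redrew %d degenerate/failed resamples", redraws)

    alpha = 1.0 - spec.ci_level
    lo, hi = 100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)
    nde_ci = tuple(np.percentile(est[:, 0], [lo, hi]))
    nie_ci = tuple(np.percentile(est[:, 1], [lo, hi]))
    total_ci = tuple(np.percentile(est.sum(axis=1), [lo, hi]))
    return replace(
        result,
        nde_ci=nde_ci, nie_ci=nie_ci, total_ci=total_ci,
        diagnostics={**result.diagnostics, "bootstrap_reps": spec.bootstrap_reps,
                     "redraws": redraws},
    )


class _DegenerateResample(RuntimeError):
    pass


class _FastEstimator:
    """Precomputed design matrices for repeated resampled estimation."""

    def __init__(self, data: pd.DataFrame, spec: MediationSpec):
        self.spec = spec
        self.Xm, _ = _design(data, spec, with_mediator=False)
        self.Xo, self.out_names = _design(data, spec, with_mediator=True)
        self.m = data["mediator"].to_numpy(float)
        self.y = data["outcome"].to_numpy(float)
        self.t = data["treatment"].to_numpy(float)
        self.i_inter = (
            self.out_names.index("treatment:mediator") if spec.interaction else None
        )

    def nde_nie(self, idx: np.ndarray) -> tuple[float, float]:
        Xm, Xo = self.Xm[idx], self.Xo[idx]
        m, y, t = self.m[idx], self.y[idx], self.t[idx]
        if self.spec.kind == "binary":
            if m.min() == m.max():
                raise _DegenerateResample
            bm, _ = logit_fit(Xm, m)
        else:
            bm, _, _ = ols_fit(Xm, m)
        bo, _, _ = ols_fit(Xo, y)
        b_t = bo[1]
        b_mcoef = bo[2]
        b_i = bo[self.i_inter] if self.i_inter is not None else 0.0
        base = Xm @ bm - bm[1] * t
        if self.spec.kind == "binary":
            p0 = _invlogit(base)
            p1 = _invlogit(base + bm[1])
            nde = b_t + b_i * float(np.mean(p0))
            nie = (b_mcoef + b_i) * float(np.mean(p1 - p0))
        else:
            nde = b_t + b_i * float(np.mean(base))
            nie = (b_mcoef + b_i) * bm[1]
        return float(nde), float(nie)


def counterfactual_oracle(
    data: pd.DataFrame,
    spec: MediationSpec,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo counterfactual estimator of NDE/NIE from the fitted models.

    Independent of the regression-formula estimator: it simulates, for
    covariate rows resampled from the analysed patients, the mediator under
    control and under treatment from the fitted mediator model, evaluates the
    fitted outcome surface at the counterfactual combinations, and averages

        NDE = E[Y(1, M(0)) - Y(0, M(0))],  NIE = E[Y(1, M(1)) - Y(1, M(0))].

    Returns point estimates with Monte-Carlo standard errors.
    """
    med = fit_mediator_model(data, spec)
    Xo, out_names = _design(data, spec, with_mediator=True)
    bo, _, _ = ols_fit(Xo, data["outcome"].to_numpy(float))
    out = pd.Series(bo, index=out_names)

    Xm, _ = _design(data, spec, with_mediator=False)
    base_all = Xm @ med.to_numpy() - med["treatment"] * data["treatment"].to_numpy(float)
    gamma_c = sum(
        (out[c] * data[c].to_numpy(float) for c in spec.covariates),
        start=np.zeros(len(data)),
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 90210]))
    rows = rng.integers(0, len(data), n_draws)
    eta0 = base_all[rows]
    eta1 = eta0 + med["treatment"]
    if spec.kind == "binary":
        m0 = (rng.random(n_draws) < _invlogit(eta0)).astype(float)
        m1 = (rng.random(n_draws) < _invlogit(eta1)).astype(float)
    else:
        resid = data["mediator"].to_numpy(float) - (
            base_all + med["treatment"] * data["treatment"].to_numpy(float)
        )
        sd_m = float(np.std(resid, ddof=Xm.shape[1]))
        noise = rng.normal(0.0, sd_m, n_draws)
        m0 = eta0 + noise
        m1 = eta1 + noise

    b_i = float(out.get("treatment:mediator", 0.0))

    def y_surface(tval: float, m: np.ndarray) -> np.ndarray:
        return (
            out["intercept"]
            + out["treatment"] * tval
            + out["mediator"] * m
            + b_i * tval * m
            + gamma_c[rows]
        )

    nde_draws = y_surface(1.0, m0) - y_surface(0.0, m0)
    nie_draws = y_surface(1.0, m1) - y_surface(1.0, m0)
    return {
        "nde": float(np.mean(nde_draws)),
        "nde_mc_se": float(np.std(nde_draws, ddof=1) / np.sqrt(n_draws)),
        "nie": float(np.mean(nie_draws)),
        "nie_mc_se": float(np.std(nie_draws, ddof=1) / np.sqrt(n_draws)),
    }


def prepare_mediation_data(
    baseline: pd.DataFrame,
    visits: pd.DataFrame,
    mediators: pd.DataFrame,
    mediator_name: str,
    active_arm: str,
    reference_arm: str = "PBO",
    landmark_week: int = 24,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Complete-case analysis frame for one active-vs-placebo contrast.

    Outcome is the FACIT change from baseline at the landmark week; patients
    with a missing landmark score or mediator are dropped (complete-case).
    """
    sub = baseline[baseline["arm"].isin([active_arm, reference_arm])].copy()
    land = visits[(visits["week"] == landmark_week)][["patient_id", "facit_score"]]
    med = mediators[mediators["mediator"] == mediator_name][["patient_id", "value"]]
    if med.empty:
        raise ValueError(f"mediator {mediator_name!r} not present in mediator table")
    df = sub.merge(land, on="patient_id").merge(med, on="patient_id")
    df["outcome"] = df["facit_score"] - df["facit_baseline"]
    df["treatment"] = (df["arm"] == active_arm).astype(float)
    df = df.rename(columns={"value": "mediator"})
    keep = ["patient_id", "treatment", "mediator", "outcome", *covariates]
    return df[keep].dropna().reset_index(drop=True)
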