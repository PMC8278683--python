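"""Mixed-effect model for repeated measures (MMRM) on FACIT-Fatigue change scores.

The model regresses the change from baseline at each post-baseline visit on
treatment, visit, their interaction, the baseline FACIT-Fatigue score and the
randomization stratification factors, with an unstructured visit-by-visit
residual covariance estimated by REML. Incomplete follow-up is handled under
the missing-at-random assumption by the likelihood itself (no imputation).
LS means are model means evaluated at the covariate grand means; contrasts
use model-based (delta-method) standard errors with between-within degrees
of freedom.

No general-purpose Python fitting routine covers this model (random-effects
packages do not expose an unstructured marginal covariance), so the REML
profile likelihood is maximised directly over a log-Cholesky
parameterisation, with a compound-symmetry fallback on non-convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._glm import RankDeficientError, _check_rank

logger = logging.getLogger(__name__)

DEFAULT_WEEKS = (4, 8, 16, 24)
DEFAULT_COVARIATES = ("facit_baseline", "strat_dmard", "strat_second")


@dataclass(frozen=True)
class MmrmConfig:
    weeks: tuple[int, ...] = DEFAULT_WEEKS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    covariance: str = "unstructured"  # or "compound_symmetry"
    reference_arm: str = "PBO"
    ci_level: float = 0.95


@dataclass
class MmrmFit:
    """Fitted MMRM: fixed effects, their covariance, and the residual covariance."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma: np.ndarray                 # visit-by-visit residual covariance
    column_names: list[str]
    arms: list[str]
    weeks: list[int]
    covariate_means: dict[str, float]
    df_between: float
    converged: bool
    covariance_used: str
    n_subjects: int
    diagnostics: dict = field(default_factory=dict)
    ci_level: float = 0.95

    def _cell_vector(self, arm: str, week: int) -> np.ndarray:
        if arm not in self.arms:
            raise ValueError(f"unknown arm {arm!r}; fit has {self.arms}")
        if week not in self.weeks:
            raise ValueError(f"unknown week {week}; fit has {self.weeks}")
        c = np.zeros(len(self.column_names))
        c[self.column_names.index("intercept")] = 1.0
        for name in (f"arm[{arm}]", f"week[{week}]", f"arm[{arm}]:week[{week}]"):
            if name in self.column_names:
                c[self.column_names.index(name)] = 1.0
        # covariates are centered at their grand means, so their contribution
        # to the LS mean is zero by construction
        return c

    def ls_means(self) -> pd.DataFrame:
        t = stats.t.ppf(0.5 + self.ci_level / 2.0, self.df_between)
        rows = []
        for arm in self.arms:
            for week in self.weeks:
                c = self._cell_vector(arm, week)
                est = float(c @ self.beta)
                se = float(np.sqrt(c @ self.cov_beta @ c))
                rows.append(
                    {
                        "arm": arm,
                        "week": week,
                        "ls_mean_change": est,
                        "se": se,
                        "ci_lower": est - t * se,
                        "ci_upper": est + t * se,
                    }
                )
        return pd.DataFrame(rows)


def ls_mean_contrast(fit: MmrmFit, week: int, arm_pair: tuple[str, str]):
    """LS-mean difference arm_pair[0] - arm_pair[1] at ``week``: (est, lo, hi, p)."""
    c = fit._cell_vector(arm_pair[0], week) - fit._cell_vector(arm_pair[1], week)
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.cov_beta @ c))
    if se == 0.0:
        return est, est, est, 1.0
    tval = est / se
    df = fit.df_between
    p = 2.0 * stats.t.sf(abs(tval), df)
    tq = stats.t.ppf(0.5 + fit.ci_level / 2.0, df)
    return est, est - tq * se, est + tq * se, float(p)


def _build_design(
    data: pd.DataFrame, arms: list[str], weeks: list[int], covariates: tuple[str, ...],
    covariate_means: dict[str, float],
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for arm in arms[1:]:
        cols.append((data["arm"] == arm).to_numpy(float))
        names.append(f"arm[{arm}]")
    for week in weeks[1:]:
        cols.append((data["week"] == week).to_numpy(float))
        names.append(f"week[{week}]")
    for arm in arms[1:]:
        for week in weeks[1:]:
            cols.append(((data["arm"] == arm) & (data["week"] == week)).to_numpy(float))
            names.append(f"arm[{arm}]:week[{week}]")
    for cov in covariates:
        cols.append(data[cov].to_numpy(float) - covariate_means[cov])
        names.append(cov)
    return np.column_stack(cols), names


def _chol_to_sigma(theta: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.diag_indices(k)] = np.exp(theta[:k])
    L[np.tril_indices(k, -1)] = theta[k:]
    return L @ L.T


def _cs_sigma(theta: np.ndarray, k: int) -> np.ndarray:
    var = np.exp(2.0 * theta[0])
    rho = np.tanh(theta[1])
    return var * ((1.0 - rho) * np.eye(k) + rho * np.ones((k, k)))


class _RemlProblem:
    """Profile REML over the residual covariance; beta solved by GLS."""

    def __init__(self, X_by_subj, y_by_subj, idx_by_subj, k: int, p: int):
        # group subjects by missingness pattern for vectorised likelihood
        self.k, self.p = k, p
        groups: dict[tuple, list[int]] = {}
        for i, idx in enumerate(idx_by_subj):
            groups.setdefault(tuple(idx), []).append(i)
        self.patterns = []
        for idx, members in groups.items():
            Xg = np.stack([X_by_subj[i] for i in members])
            Yg = np.stack([y_by_subj[i] for i in members])
            self.patterns.append((np.array(idx, dtype=int), Xg, Yg))

    def neg2_reml(self, sigma: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        p = self.p
        A = np.zeros((p, p))
        b = np.zeros(p)
        ysy = 0.0
        logdet = 0.0
        for idx, Xg, Yg in self.patterns:
            S = sigma[np.ix_(idx, idx)]
            sign, ld = np.linalg.slogdet(S)
            if sign <= 0:
                return np.inf, np.full(p, np.nan), A
            Sinv = np.linalg.inv(S)
            logdet += Xg.shape[0] * ld
            A += np.einsum("ikp,kl,ilq->pq", Xg, Sinv, Xg, optimize=True)
            b += np.einsum("ikp,kl,il->p", Xg, Sinv, Yg, optimize=True)
            ysy += float(np.einsum("ik,kl,il->", Yg, Sinv, Yg, optimize=True))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, np.full(p, np.nan), A
        quad = ysy - float(b @ beta)
        sign_a, ld_a = np.linalg.slogdet(A)
        if sign_a <= 0:
            return np.inf, beta, A
        return logdet + quad + ld_a, beta, A


def fit_mmrm(
    changes: pd.DataFrame,
    baselines: pd.DataFrame,
    config: MmrmConfig | None = None,
) -> MmrmFit:
    """Fit the MMRM on long-format change scores.

    ``changes`` columns: patient_id, week, change (NaN/absent rows = missing).
    ``baselines`` columns: patient_id, arm, plus the configured covariates.
    Deterministic for fixed input; raises on a singular design, naming the
    aliased term.
    """
    config = config or MmrmConfig()
    data = changes.merge(baselines, on="patient_id", how="inner")
    data = data[data["week"].isin(config.weeks)].dropna(subset=["change"])
    data = data.sort_values(["patient_id", "week"], kind="mergesort").reset_index(drop=True)

    arms = sorted(data["arm"].unique(), key=lambda a: (a != config.reference_arm, a))
    if len(arms) < 2:
        raise ValueError("MMRM requires at least two arms")
    weeks = sorted(set(config.weeks) & set(data["week"].unique()))
    covariate_means = {c: float(data[c].mean()) for c in config.covariates}

    X, names = _build_design(data, arms, list(weeks), config.covariates, covariate_means)
    try:
        _check_rank(X)
    except RankDeficientError as e:
        raise RankDeficientError(e.column, f"aliased model term: {names[e.column]}") from None

    week_pos = {w: j for j, w in enumerate(weeks)}
    X_by, y_by, idx_by = [], [], []
    for _, g in data.groupby("patient_id", sort=True):
        rows = g.index.to_numpy()
        idx_by.append([week_pos[w] for w in g["week"]])
        X_by.append(X[rows])
        y_by.append(g["change"].to_numpy())
    n_subj = len(X_by)
    k, p = len(weeks), X.shape[1]
    problem = _RemlProblem(X_by, y_by, idx_by, k, p)

    # moment-based start: per-week residual variances, common correlation 0.5
    resid_var = []
    for w in weeks:
        yv = data.loc[data["week"] == w, "change"]
        resid_var.append(max(float(yv.var(ddof=1)), 1e-3))
    start_sigma = np.sqrt(resid_var)

    def _optimize(structure: str):
        if structure == "unstructured":
            theta0 = np.concatenate([np.log(start_sigma), np.zeros(k * (k - 1) // 2)])
            to_sigma = lambda th: _chol_to_sigma(th, k)
        else:
            theta0 = np.array([np.log(np.mean(start_sigma)), np.arctanh(0.5)])
            to_sigma = lambda th: _cs_sigma(th, k)
        res = optimize.minimize(
            lambda th: problem.neg2_reml(to_sigma(th))[0],
            theta0,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        return res, to_sigma(res.x)

    structure = config.covariance
    res, sigma = _optimize(structure)
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged and structure == "unstructured":
        logger.warning(
            "unstructured REML did not converge (%s); falling back to compound symmetry",
            res.message,
        )
        structure = "compound_symmetry"
        res, sigma = _optimize(structure)
        converged = bool(res.success) and np.isfinite(res.fun)

    _, beta, A = problem.neg2_reml(sigma)
    cov_beta = np.linalg.inv(A)

    # between-within df: arm contrasts are between-subject comparisons
    n_between_params = len(arms) + len(config.covariates)
    df_between = float(n_subj - n_between_params)

    fit = MmrmFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma=sigma,
        column_names=names,
        arms=list(arms),
        weeks=list(weeks),
        covariate_means=covariate_means,
        df_between=df_between,
        converged=converged,
        covariance_used=structure,
        n_subjects=n_subj,
        diagnostics={"neg2_reml": float(res.fun), "message": str(res.message)},
        ci_level=config.ci_level,
    )
    if not converged:
        logger.warning("MMRM flagged non-converged: %s", res.message)
    return fit
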