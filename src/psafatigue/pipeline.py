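"""End-to-end orchestration: simulate -> endpoints -> MMRM -> responders -> effect sizes -> mediation.

Each stage reads only data frames produced upstream, never mutating files on
disk; a single config seed fans out deterministically to per-stage child
seeds so any stage can be reproduced in isolation. Outputs are delimited
text tables plus one machine-readable ``results.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import effect_size, endpoints, io, mediation, mmrm, responders, synthetic
from .config import RunConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "endpoints", "mmrm", "responders", "effect_sizes", "mediation")


def _child_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES), dtype=np.uint64)
    return {stage: int(s % (2**31)) for stage, s in zip(STAGES, state)}


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; writes tables under config.out_dir, returns results dict."""
    config.validate()
    seeds = _child_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_seed": config.seed}

    if config.input_dir is not None:
        trial = io.read_trial(config.input_dir)
    else:
        sim_cfg = config.simulate
        trial = _simulate(sim_cfg, seeds["simulate"] if sim_cfg.seed == 0 else sim_cfg.seed)
        io.write_trial(trial, out / "data")
    results["truth"] = {
        "mediator_name": trial.truth.mediator_name,
        "true_nde": trial.truth.true_nde,
        "true_nie": trial.truth.true_nie,
        "true_total": trial.truth.true_total,
    }

    endpoint_table = _endpoints(trial)
    endpoint_table.to_csv(out / "endpoints.csv", index=False)

    land = config.analysis.landmark_week
    changes = synthetic.change_scores(trial.visits)

    fit, ls_means, contrasts = _mmrm(changes, trial.baseline, land)
    ls_means.to_csv(out / "ls_means.csv", index=False)
    contrasts.to_csv(out / "ls_contrasts.csv", index=False)
    results["mmrm"] = {
        "converged": fit.converged,
        "covariance": fit.covariance_used,
        "contrasts": contrasts.to_dict("records"),
    }

    resp_summary, resp_contrasts, curve = _responders(
        changes, trial.baseline, land, config.analysis.responder_threshold
    )
    resp_summary.to_csv(out / "responders.csv", index=False)
    resp_contrasts.to_csv(out / "responder_contrasts.csv", index=False)
    curve.as_frame().to_csv(out / "cdf_curves.csv", index=False)
    results["responders"] = {
        "summary": resp_summary.to_dict("records"),
        "contrasts": resp_contrasts.to_dict("records"),
    }

    es_table = _effect_sizes(changes, trial.baseline, weeks=(land, 52))
    es_table.to_csv(out / "effect_sizes.csv", index=False)
    results["effect_sizes"] = es_table.to_dict("records")

    med_table, med_records = _mediation(trial, config, seeds["mediation"], land)
    med_table.to_csv(out / "mediation.csv", index=False)
    results["mediation"] = med_records

    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float) + "\n"
    )
    logger.info("pipeline complete; outputs in %s", out)
    return results


@_stage("simulate")
def _simulate(sim_cfg, seed: int):
    return synthetic.generate_trial(sim_cfg, seed=seed)


@_stage("endpoints")
def _endpoints(trial):
    return endpoints.derive_endpoint_table(trial.components)


@_stage("mmrm")
def _mmrm(changes, baseline, landmark_week):
    weeks = tuple(w for w in mmrm.DEFAULT_WEEKS if w <= landmark_week)
    fit = mmrm.fit_mmrm(changes, baseline, mmrm.MmrmConfig(weeks=weeks))
    ls_means = fit.ls_means()
    rows = []
    for arm in fit.arms:
        if arm == "PBO":
            continue
        for week in fit.weeks:
            est, lo, hi, p = mmrm.ls_mean_contrast(fit, week, (arm, "PBO"))
            rows.append(
                {"contrast": f"{arm} vs PBO", "week": week, "estimate": est,
                 "ci_lower": lo, "ci_upper": hi, "p_value": p}
            )
    return fit, ls_means, pd.DataFrame(rows)


@_stage("responders")
def _responders(changes, baseline, landmark_week, threshold):
    land = changes[changes["week"] == landmark_week][["patient_id", "change"]]
    flags = baseline[["patient_id", "arm", "strat_dmard", "strat_second"]].merge(
        land, on="patient_id", how="left"
    )
    # missing landmark change = non-responder (non-responder imputation)
    flags["responder"] = (flags["change"] >= threshold).fillna(False).astype(int)
    flags["stratum"] = (
        flags["strat_dmard"].astype(int).astype(str)
        + "/"
        + flags["strat_second"].astype(int).astype(str)
    )
    summary, contrasts = responders.responder_table(flags)
    changes_by_arm = {
        arm: g["change"].to_numpy() for arm, g in flags.groupby("arm")
    }
    curve = responders.cumulative_curve(changes_by_arm)
    return summary, contrasts, curve


@_stage("effect_sizes")
def _effect_sizes(changes, baseline, weeks):
    rows = []
    for arm, g in baseline.groupby("arm"):
        sd = float(g["facit_baseline"].std(ddof=1))
        for week in weeks:
            ch = changes[
                (changes["week"] == week)
                & changes["patient_id"].isin(g["patient_id"])
            ]["change"].dropna()
            if ch.empty:
                continue
            res = effect_size.EffectSizeResult(
                arm=arm, week=week, mean_change=float(ch.mean()), baseline_sd=sd
            )
            rows.append(
                {"arm": arm, "week": week, "n": len(ch),
                 "mean_change": res.mean_change, "baseline_sd": sd,
                 "cohens_d": res.d_reported, "magnitude": res.magnitude}
            )
    return pd.DataFrame(rows)


@_stage("mediation")
def _mediation(trial, config: RunConfig, seed: int, landmark_week: int):
    rows, records = [], []
    for i, name in enumerate(config.analysis.mediators):
        for j, arm in enumerate(("Q4W", "Q8W")):
            data = mediation.prepare_mediation_data(
                trial.baseline, trial.visits, trial.mediators,
                mediator_name=name, active_arm=arm, landmark_week=landmark_week,
            )
            spec = mediation.MediationSpec(
                mediator_name=name,
                bootstrap_reps=config.analysis.bootstrap_reps,
                ci_level=config.analysis.ci_level,
                seed=(seed + 13 * i + j) % (2**31),
            )
            res = mediation.bootstrap_mediation(data, spec)
            star = lambda ci: "*" if ci is not None and (ci[0] > 0 or ci[1] < 0) else ""
            rows.append(
                {
                    "mediator": name, "contrast": f"{arm} vs PBO", "n": len(data),
                    "nde": res.nde, "nde_lo": res.nde_ci[0], "nde_hi": res.nde_ci[1],
                    "nde_sig": star(res.nde_ci),
                    "nie": res.nie, "nie_lo": res.nie_ci[0], "nie_hi": res.nie_ci[1],
                    "nie_sig": star(res.nie_ci),
                    "total": res.total, "total_lo": res.total_ci[0],
                    "total_hi": res.total_ci[1], "total_sig": star(res.total_ci),
                    "pct_indirect": None if res.pct_indirect is None
                    else round(res.pct_indirect, 1),
                    "pct_direct": None if res.pct_direct is None
                    else round(res.pct_direct, 1),
                }
            )
            records.append(rows[-1])
    return pd.DataFrame(rows), records
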