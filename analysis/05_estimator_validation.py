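"""Validation of the mediation estimator against its independent oracles,
at reduced replicate counts suitable for an interactive run (the test suite
runs the full-size versions):

1. regression-formula NDE/NIE vs the Monte-Carlo counterfactual simulator;
2. bias of NDE/NIE across replicated trials against the generator truth;
3. additivity NDE + NIE = total-effect regression coefficient (continuous
   mediator, machine precision)."""

import numpy as np

from psafatigue import mediation as med, synthetic as syn


def main() -> None:
    cfg = syn.TrialConfig(n_per_arm={"Q4W": 400, "PBO": 400})
    trial = syn.generate_trial(cfg, seed=55)

    print("-- oracle agreement --")
    for mediator in ("ACR20", "dCRP"):
        frame = med.prepare_mediation_data(
            trial.baseline, trial.visits, trial.mediators, mediator, "Q4W"
        )
        spec = med.MediationSpec(mediator)
        r = med.estimate_nde_nie(frame, spec)
        o = med.counterfactual_oracle(frame, spec, n_draws=500_000, seed=1)
        print(f"  {mediator}: NDE {r.nde:.3f} vs oracle {o['nde']:.3f} "
              f"(MC SE {o['nde_mc_se']:.4f}); "
              f"NIE {r.nie:.3f} vs oracle {o['nie']:.3f} "
              f"(MC SE {o['nie_mc_se']:.4f})")

    print("-- replicated-trial bias (100 reps, n=1000/arm) --")
    big = syn.TrialConfig(n_per_arm={"Q4W": 1000, "PBO": 1000})
    truth = syn.generate_trial(big, seed=1).truth
    ests = np.empty((100, 2))
    for r_i in range(100):
        t = syn.generate_trial(big, seed=60_000 + r_i)
        frame = med.prepare_mediation_data(
            t.baseline, t.visits, t.mediators, "ACR20", "Q4W"
        )
        res = med.estimate_nde_nie(frame, med.MediationSpec("ACR20"))
        ests[r_i] = (res.nde, res.nie)
    bias = ests.mean(axis=0) - (truth.true_nde, truth.true_nie)
    se = ests.std(axis=0, ddof=1) / 10
    print(f"  NDE bias {bias[0]:+.3f} (MC SE {se[0]:.3f}); "
          f"NIE bias {bias[1]:+.3f} (MC SE {se[1]:.3f})")

    print("-- additivity, continuous mediator --")
    frame = med.prepare_mediation_data(
        trial.baseline, trial.visits, trial.mediators, "dCRP", "Q4W"
    )
    r = med.estimate_nde_nie(frame, med.MediationSpec("dCRP"))
    gap = r.nde + r.nie - r.total_regression
    print(f"  NDE+NIE - total coefficient = {gap:.2e}")


if __name__ == "__main__":
    main()
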