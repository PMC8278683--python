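"""Mediation decomposition of the week-24 treatment effect on FACIT-Fatigue
through each clinical response (ACR20, MDA, change in CRP), per study and
per active-vs-placebo contrast, with percentile-bootstrap 95% CIs (B=1000).

The report mirrors the published layout: NDE, NIE and total effect with CIs
and significance stars, plus percent direct/indirect. Expect the NDE to
dominate for the default generator (true percent indirect ~ 31%) and the
estimated total to sit near the generator's true total effect."""

from pathlib import Path

import pandas as pd

from psafatigue import io, mediation as med

ROOT = Path(__file__).resolve().parent.parent / "results"
TABLES = ROOT / "tables"
SEED = 2718


def star(ci):
    return "*" if ci[0] > 0 or ci[1] < 0 else ""


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in ("d1", "d2"):
        trial = io.read_trial(ROOT / "data" / study)
        for i, mediator in enumerate(("ACR20", "MDA", "dCRP")):
            for j, arm in enumerate(("Q4W", "Q8W")):
                frame = med.prepare_mediation_data(
                    trial.baseline, trial.visits, trial.mediators, mediator, arm
                )
                spec = med.MediationSpec(
                    mediator, bootstrap_reps=1000,
                    seed=SEED + 100 * (study == "d2") + 10 * i + j,
                )
                r = med.bootstrap_mediation(frame, spec)
                rows.append({
                    "study": study.upper(), "mediator": mediator,
                    "contrast": f"{arm} vs PBO", "n": len(frame),
                    "nde": round(r.nde, 2), "nde_ci": [round(x, 2) for x in r.nde_ci],
                    "nde_sig": star(r.nde_ci),
                    "nie": round(r.nie, 2), "nie_ci": [round(x, 2) for x in r.nie_ci],
                    "nie_sig": star(r.nie_ci),
                    "total": round(r.total, 2),
                    "total_ci": [round(x, 2) for x in r.total_ci],
                    "pct_indirect": round(r.pct_indirect, 1),
                    "pct_direct": round(r.pct_direct, 1),
                })
    table = pd.DataFrame(rows)
    table.to_csv(TABLES / "mediation.csv", index=False)
    for _, r in table.iterrows():
        print(f"{r['study']} {r['mediator']:>5} {r['contrast']}: "
              f"NDE {r['nde']}{r['nde_sig']} NIE {r['nie']}{r['nie_sig']} "
              f"total {r['total']}  %indirect {r['pct_indirect']}")


if __name__ == "__main__":
    main()
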