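"""Delimited-text readers/writers for the trial tables.

All files are comma-separated UTF-8 with a header row; missing values are
empty fields. One baseline file, one long-format visit file, one long-format
mediator file, one component-panel file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import TrialData, SimulationTruth

FILES = {
    "baseline": "baseline.csv",
    "visits": "visits.csv",
    "mediators": "mediators.csv",
    "components": "components.csv",
}


def write_trial(trial: TrialData, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in FILES.items():
        path = out_dir / fname
        getattr(trial, name).to_csv(path, index=False, na_rep="")
        paths[name] = path
    truth = trial.truth
    truth_frame = pd.DataFrame(
        [
            {
                "mediator_name": truth.mediator_name,
                "true_nde": truth.true_nde,
                "true_nie": truth.true_nie,
                "true_total": truth.true_total,
            }
        ]
    )
    paths["truth"] = out_dir / "simulation_truth.csv"
    truth_frame.to_csv(paths["truth"], index=False)
    return paths


def read_trial(in_dir: str | Path) -> TrialData:
    in_dir = Path(in_dir)
    tables = {name: pd.read_csv(in_dir / fname) for name, fname in FILES.items()}
    truth_path = in_dir / "simulation_truth.csv"
    if truth_path.exists():
        row = pd.read_csv(truth_path).iloc[0]
        truth = SimulationTruth(
            mediator_name=str(row["mediator_name"]),
            true_nde=float(row["true_nde"]),
            true_nie=float(row["true_nie"]),
            true_total=float(row["true_total"]),
            generator_params={},
        )
    else:
        truth = SimulationTruth("unknown", 0.0, 0.0, 0.0, {})
    return TrialData(truth=truth, **tables)
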