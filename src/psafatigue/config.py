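"""Run configuration: simulate block + analysis block, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import TrialConfig, VISIT_WEEKS, MEDIATOR_KINDS


@dataclass(frozen=True)
class AnalysisConfig:
    landmark_week: int = 24
    responder_threshold: float = 4.0
    mediators: tuple[str, ...] = ("ACR20", "MDA", "dCRP")
    bootstrap_reps: int = 1000
    ci_level: float = 0.95

    def validate(self) -> None:
        if self.landmark_week not in VISIT_WEEKS:
            raise ValueError(
                f"landmark week {self.landmark_week} not in visit schedule {VISIT_WEEKS}"
            )
        if self.responder_threshold <= 0:
            raise ValueError("responder threshold must be > 0")
        unknown = set(self.mediators) - set(MEDIATOR_KINDS)
        if unknown:
            raise ValueError(f"unknown mediator name(s): {sorted(unknown)}")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    simulate: TrialConfig | None = field(default_factory=TrialConfig)
    input_dir: str | None = None          # read an existing dataset instead
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config needs either a simulate block or input_dir")
        self.analysis.validate()


def load_config(path: str | Path, **overrides) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    sim_raw = raw.pop("simulate", None)
    ana_raw = raw.pop("analysis", {})
    cfg = RunConfig(
        simulate=TrialConfig(**sim_raw) if sim_raw is not None else (
            None if raw.get("input_dir") else TrialConfig()
        ),
        analysis=AnalysisConfig(
            **{k: tuple(v) if k == "mediators" else v for k, v in ana_raw.items()}
        ),
        **raw,
    )
    cfg.validate()
    return cfg
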