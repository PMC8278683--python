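"""Generate the two synthetic studies (D1-like and D2-like) used by the
downstream analyses, write their delimited-text tables under results/data/,
and summarise how the baselines compare with the published marginals."""

from pathlib import Path

from psafatigue import io, synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

N_PER_ARM = {
    "D1": {"Q4W": 128, "Q8W": 127, "PBO": 126},
    "D2": {"Q4W": 245, "Q8W": 248, "PBO": 246},
}
SEED = {"D1": 101, "D2": 102}


def main() -> None:
    for study in ("D1", "D2"):
        cfg = syn.TrialConfig(study=study, n_per_arm=N_PER_ARM[study], seed=SEED[study])
        trial = syn.generate_trial(cfg)
        io.write_trial(trial, OUT / study.lower())
        b = trial.baseline
        print(f"--- {study}: n={len(b)} ---")
        print(
            f"baseline FACIT mean (SD): {b.facit_baseline.mean():.1f} "
            f"({b.facit_baseline.std(ddof=1):.1f})  "
            f"[published range 29.1-31.4 (9.5-11.3)]"
        )
        print(
            f"ground truth: NDE={trial.truth.true_nde:.2f}, "
            f"NIE={trial.truth.true_nie:.2f}, total={trial.truth.true_total:.2f} "
            f"via {trial.truth.mediator_name}"
        )
    print(f"\ntables written under {OUT}")


if __name__ == "__main__":
    main()
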