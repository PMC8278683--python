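import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from psafatigue import synthetic as syn
from psafatigue import mediation as med

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def d2_trial():
    """Default-condition synthetic study (three arms, published arm sizes)."""
    return syn.generate_trial(syn.TrialConfig(seed=12345))


@pytest.fixture(scope="session")
def two_arm_trial():
    """Two-arm trial at a size where single fits are quick but stable."""
    cfg = syn.TrialConfig(n_per_arm={"Q4W": 400, "PBO": 400})
    return syn.generate_trial(cfg, seed=2024)


@pytest.fixture(scope="session")
def acr20_frame(two_arm_trial):
    t = two_arm_trial
    return med.prepare_mediation_data(
        t.baseline, t.visits, t.mediators, "ACR20", "Q4W"
    )


@pytest.fixture(scope="session")
def dcrp_frame(two_arm_trial):
    t = two_arm_trial
    return med.prepare_mediation_data(
        t.baseline, t.visits, t.mediators, "dCRP", "Q4W"
    )


def make_visits(records):
    """Small long-format visit table from (patient_id, week, score) tuples."""
    return pd.DataFrame(records, columns=["patient_id", "week", "facit_score"]).assign(
        failed=0
    )
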