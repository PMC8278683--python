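"""Composite clinical endpoints: ACR20, minimal disease activity, FACIT response.

ACR20 requires >=20% improvement in both tender and swollen joint counts plus
>=20% improvement in at least 3 of 5 ancillary measures (patient pain, patient
global assessment of arthritis, physician global assessment, HAQ-DI, CRP).
MDA is met when at least 5 of 7 criteria hold (tender joints <=1, swollen
joints <=1, PASI <=1, pain <=1.5 cm, patient global <=2.0 cm, HAQ-DI <=0.5,
tender entheseal points <=1). A FACIT-Fatigue responder improves by >=4 points.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

ACR_CORE = ("tjc", "sjc")
ACR_ANCILLARY = ("pain", "ptga_arthritis", "pga", "haqdi", "crp")

MDA_CRITERIA: dict[str, float] = {
    "tjc": 1.0,
    "sjc": 1.0,
    "pasi": 1.0,
    "pain": 1.5,
    "ptga_arthritis": 2.0,
    "haqdi": 0.5,
    "tender_entheseal_points": 1.0,
}

FACIT_RESPONSE_THRESHOLD = 4.0


def _present(panel: Mapping[str, float], key: str) -> bool:
    v = panel.get(key)
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def _improved_20pct(base: float, land: float) -> bool:
    # A zero baseline makes percent improvement undefined; the component is
    # counted as improved only if it did not worsen (keeps monotonicity and
    # avoids division by zero). The boundary is inclusive: exactly 20%
    # improvement counts, with a relative tolerance so that values computed
    # as base*0.8 are not lost to floating-point rounding.
    if base == 0:
        return land <= base
    return (base - land) / base >= 0.20 - 1e-12


def acr20(baseline: Mapping[str, float], landmark: Mapping[str, float]) -> bool:
    """>=20% improvement in both joint counts and in >=3 of 5 ancillary measures."""
    for key in ACR_CORE:
        if not (_present(baseline, key) and _present(landmark, key)):
            raise ValueError(f"ACR20 requires {key} at both timepoints")
    avail = [
        k for k in ACR_ANCILLARY if _present(baseline, k) and _present(landmark, k)
    ]
    if len(avail) < 3:
        raise ValueError(
            "ACR20 requires >=3 of the 5 ancillary measures at both timepoints; "
            f"only {len(avail)} present"
        )
    if not all(_improved_20pct(baseline[k], landmark[k]) for k in ACR_CORE):
        return False
    n_improved = sum(_improved_20pct(baseline[k], landmark[k]) for k in avail)
    return n_improved >= 3


def mda(landmark: Mapping[str, float]) -> bool:
    """Minimal disease activity: >=5 of the 7 cut-off criteria satisfied."""
    for key in MDA_CRITERIA:
        if not _present(landmark, key):
            raise ValueError(f"MDA criterion input missing: {key}")
    n_met = sum(landmark[k] <= cut for k, cut in MDA_CRITERIA.items())
    return n_met >= 5


def facit_responder(change: float) -> bool:
    """Clinically meaningful fatigue improvement: change >= 4 points."""
    if not math.isfinite(change):
        raise ValueError("change must be finite")
    return change >= FACIT_RESPONSE_THRESHOLD


def derive_endpoint_table(components: pd.DataFrame) -> pd.DataFrame:
    """Per-patient ACR20/MDA flags from a long component panel.

    ``components`` carries one baseline and one landmark row per patient
    (column ``timepoint``) with the component columns used by both endpoints.
    """
    wide = components.set_index(["patient_id", "timepoint"])
    base = wide.xs("baseline", level="timepoint")
    land = wide.xs("landmark", level="timepoint")
    rows = []
    for pid in base.index:
        b = base.loc[pid].to_dict()
        l = land.loc[pid].to_dict()
        rows.append(
            {
                "patient_id": pid,
                "acr20": int(acr20(b, l)),
                "mda": int(mda(l)),
            }
        )
    return pd.DataFrame(rows)
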