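"""Responder proportions, stratified CMH tests, Wald CIs and threshold-sweep curves.

Responder analyses compare the proportion of patients reaching a clinically
meaningful FACIT-Fatigue improvement (>=4 points) between each active arm
and placebo with a Cochran-Mantel-Haenszel test stratified by the
randomization factors; missing landmark responses count as non-responders.
The cumulative curves sweep the improvement threshold over the integers
0..20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(range(0, 21))


@dataclass(frozen=True)
class CmhResult:
    statistic: float
    p_value: float
    n_strata_used: int


def cmh_test(responder: np.ndarray, treated: np.ndarray, stratum: np.ndarray) -> CmhResult:
    """CMH chi-square (1 df) over per-stratum 2x2 tables, no continuity correction.

    Uses the Cochran variance convention, ``sum n1*n0*m1*m0 / n^3`` per
    stratum, under which the single-stratum statistic reduces exactly to the
    Pearson chi-square of the 2x2 table. (The Mantel-Haenszel hypergeometric
    convention differs by a per-stratum factor (n-1)/n; the test suite ties
    the two together.) Strata whose 2x2 table has a zero margin carry no
    information and are dropped with a log message.
    """
    responder = np.asarray(responder, dtype=bool)
    treated = np.asarray(treated, dtype=bool)
    stratum = np.asarray(stratum)
    num = 0.0
    var = 0.0
    used = 0
    dropped = 0
    for s in pd.unique(stratum):
        m = stratum == s
        a = float(np.sum(responder[m] & treated[m]))
        n1 = float(np.sum(treated[m]))
        n0 = float(np.sum(m) - n1)
        m1 = float(np.sum(responder[m]))
        n = n1 + n0
        m0 = n - m1
        if min(n1, n0, m1, m0) == 0:
            dropped += 1
            logger.info("dropping stratum %r: zero margin in its 2x2 table", s)
            continue
        num += a - n1 * m1 / n
        var += n1 * n0 * m1 * m0 / n**3
        used += 1
    if used == 0:
        raise ValueError("no informative stratum remains")
    if dropped:
        logger.info("CMH test used %d strata (%d dropped)", used, dropped)
    statistic = num**2 / var
    p = float(stats.chi2.sf(statistic, df=1))
    return CmhResult(float(statistic), p, used)


def wald_ci_diff(
    p1: float, n1: int, p0: float, n0: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Difference in proportions with Wald CI: diff +/- z*sqrt(p1q1/n1 + p0q0/n0)."""
    for p in (p1, p0):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    if min(n1, n0) < 1:
        raise ValueError("sample sizes must be >= 1")
    diff = p1 - p0
    se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return diff, diff - z * se, diff + z * se


@dataclass(frozen=True)
class CdfCurve:
    """Per-arm proportions achieving improvement >= t for each threshold t."""

    thresholds: tuple[int, ...]
    proportions: dict[str, np.ndarray]

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"threshold": self.thresholds})
        for arm, props in self.proportions.items():
            out[arm] = props
        return out


def cumulative_curve(
    changes_by_arm: dict[str, np.ndarray],
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> CdfCurve:
    """Proportion of patients per arm with change >= threshold.

    Missing landmark changes (NaN) are kept in the denominator and count as
    non-achievers at every threshold (non-responder imputation).
    """
    props = {}
    for arm, changes in changes_by_arm.items():
        changes = np.asarray(changes, dtype=float)
        if changes.size == 0:
            raise ValueError(f"arm {arm!r} has no patients")
        achieved = np.nan_to_num(changes, nan=-np.inf)
        props[arm] = np.array(
            [np.mean(achieved >= t) for t in thresholds]
        )
    return CdfCurve(tuple(thresholds), props)


def responder_table(
    flags: pd.DataFrame,
    reference_arm: str = "PBO",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-arm responder summary plus stratified contrasts vs the reference arm.

    ``flags`` columns: patient_id, arm, responder (0/1), stratum.
    """
    rows = []
    by_arm = flags.groupby("arm")
    summaries = {
        arm: (len(g), int(g["responder"].sum())) for arm, g in by_arm
    }
    for arm, (n, r) in summaries.items():
        rows.append({"arm": arm, "n": n, "responders": r, "proportion": r / n})
    summary = pd.DataFrame(rows)

    contrasts = []
    n0, r0 = summaries[reference_arm]
    for arm, (n1, r1) in summaries.items():
        if arm == reference_arm:
            continue
        sub = flags[flags["arm"].isin([arm, reference_arm])]
        cmh = cmh_test(
            sub["responder"].to_numpy(),
            (sub["arm"] == arm).to_numpy(),
            sub["stratum"].to_numpy(),
        )
        diff, lo, hi = wald_ci_diff(r1 / n1, n1, r0 / n0, n0, level)
        contrasts.append(
            {
                "contrast": f"{arm} vs {reference_arm}",
                "diff": diff,
                "ci_lower": lo,
                "ci_upper": hi,
                "cmh_statistic": cmh.statistic,
                "p_value": cmh.p_value,
            }
        )
    return summary, pd.DataFrame(contrasts)
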