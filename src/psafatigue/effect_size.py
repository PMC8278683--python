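"""Cohen's-d effect sizes for observed FACIT-Fatigue change scores.

The effect size divides the observed mean change from baseline by the SD of
baseline scores in the same arm; 0.20 / 0.50 / 0.80 mark the conventional
small / moderate / large boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

MAGNITUDE_BOUNDS = ((0.20, "negligible"), (0.50, "small"), (0.80, "moderate"))


def cohens_d(mean_change: float, baseline_sd: float) -> float:
    """Exact quotient mean_change / baseline_sd (unrounded)."""
    if baseline_sd <= 0:
        raise ValueError("baseline SD must be positive")
    return mean_change / baseline_sd


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for reported values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


def classify_magnitude(d: float) -> str:
    """Label |d|: <0.20 negligible, [0.20,0.50) small, [0.50,0.80) moderate, >=0.80 large."""
    a = abs(d)
    for bound, label in MAGNITUDE_BOUNDS:
        if a < bound:
            return label
    return "large"


@dataclass(frozen=True)
class EffectSizeResult:
    arm: str
    week: int
    mean_change: float
    baseline_sd: float

    @property
    def d(self) -> float:
        return cohens_d(self.mean_change, self.baseline_sd)

    @property
    def d_reported(self) -> float:
        return round_half_away(self.d, 2)

    @property
    def magnitude(self) -> str:
        return classify_magnitude(self.d)
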