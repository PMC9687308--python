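"""Incremental cost-effectiveness: deltas, ICER/ICUR, dominance, NMB.

Ratios are carried at full precision and rounded to the nearest euro only
for display. When the incremental effect is zero (or the pair sits in a
quadrant where a ratio is meaningless, e.g. negative incremental QALY),
the ratio is reported as a sentinel (NaN) with the dominance label
carrying the interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import math
from pathlib import Path

from .markov_engine import ArmResult

__all__ = ["CEResult", "compare", "compare_deltas"]

DOMINANT = "intervention-dominant"
DOMINATED = "intervention-dominated"
NO_DOMINANCE = "none"


@dataclass
class CEResult:
    """Incremental results for intervention minus comparator."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer: float  # EUR per LY gained; NaN when delta_ly <= 0
    icur: float  # EUR per QALY gained; NaN when delta_qaly <= 0
    dominance: str
    nmb: float
    wtp: float

    @property
    def icer_rounded(self) -> float:
        return round(self.icer) if math.isfinite(self.icer) else math.nan

    @property
    def icur_rounded(self) -> float:
        return round(self.icur) if math.isfinite(self.icur) else math.nan

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer": None if math.isnan(self.icer) else self.icer,
            "icur": None if math.isnan(self.icur) else self.icur,
            "dominance": self.dominance,
            "nmb": self.nmb,
            "wtp": self.wtp,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _ratio(delta_cost: float, delta_effect: float) -> float:
    if delta_effect > 0:
        return delta_cost / delta_effect
    return math.nan


def compare(intervention: ArmResult, comparator: ArmResult,
            wtp: float) -> CEResult:
    """Pairwise incremental comparison at a willingness-to-pay threshold.

    Deltas are intervention minus comparator. The intervention dominates
    iff it is cheaper and more effective (positive incremental QALY);
    it is dominated in the mirror case. NMB = wtp * dQALY - dcost.
    """
    return compare_deltas(intervention.total_cost - comparator.total_cost,
                          intervention.ly - comparator.ly,
                          intervention.qaly - comparator.qaly, wtp)


def compare_deltas(d_cost: float, d_ly: float, d_qaly: float,
                   wtp: float) -> CEResult:
    """Build a :class:`CEResult` directly from incremental totals (useful
    for checking published incremental tables)."""

    if d_cost < 0 and d_qaly > 0:
        dominance = DOMINANT
    elif d_cost > 0 and d_qaly < 0:
        dominance = DOMINATED
    else:
        dominance = NO_DOMINANCE

    return CEResult(
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer=_ratio(d_cost, d_ly),
        icur=_ratio(d_cost, d_qaly),
        dominance=dominance,
        nmb=wtp * d_qaly - d_cost,
        wtp=wtp,
    )
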