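"""Risk equations, composite-event splitting, and background mortality.

The base-case engine is the SMART recurrent-event equation: a Cox model
over the cohort's risk-factor profile whose 10-year composite risk of a
major cardiovascular event (MI, stroke or CV death) is

    risk10 = 1 - S0 ** exp(lp)

with ``lp`` the centred linear predictor and ``S0`` the 10-year baseline
survival. Coefficients live in a CSV data file (columns ``covariate``,
``transform``, ``coefficient``) so transcription corrections never require
a code change; supported transforms are ``identity``, ``indicator``
(identity applied to a prevalence fraction), ``log``, ``square`` and
``offset`` (a constant added to the linear predictor, e.g. a centring
term).

Because neither a SMART-style composite nor the Framingham equations
distinguish event type or fatality, the composite per-cycle probability is
split by a country-level CHD share and case-fatality fractions
(:class:`EpidemiologyParams`). Non-cardiovascular mortality comes from a
general-population life table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import EpidemiologyParams

logger = logging.getLogger(__name__)

__all__ = [
    "CoefficientTerm",
    "RiskModelSpec",
    "LifeTable",
    "EventSplit",
    "load_coefficients",
    "linear_predictor",
    "smart_linear_predictor",
    "horizon_risk",
    "risk_to_cycle_prob",
    "split_composite",
    "noncv_death_prob",
    "smart_cycle_probs",
    "framingham_cycle_probs",
]

_TRANSFORMS = ("identity", "indicator", "log", "square", "offset")

_warned_degenerate_risk = False


@dataclass
class CoefficientTerm:
    """One additive term of a risk-equation linear predictor."""

    covariate: str
    transform: str
    coefficient: float

    def evaluate(self, profile) -> float:
        if self.transform == "offset":
            return self.coefficient
        try:
            x = getattr(profile, self.covariate)
        except AttributeError:
            raise ConfigurationError(
                f"risk-equation covariate '{self.covariate}' is not a "
                "cohort-profile field") from None
        if self.transform in ("identity", "indicator"):
            return self.coefficient * x
        if self.transform == "log":
            if x <= 0:
                raise ConfigurationError(
                    f"log transform of non-positive covariate "
                    f"'{self.covariate}' = {x}")
            return self.coefficient * math.log(x)
        if self.transform == "square":
            return self.coefficient * x * x
        raise ConfigurationError(f"unknown transform '{self.transform}'")


@dataclass
class RiskModelSpec:
    """A named risk equation: coefficient terms plus baseline survival over
    a stated horizon (10 years for SMART)."""

    name: str
    coefficients: list[CoefficientTerm]
    baseline_survival: float
    horizon_years: float
    source_file: str = ""

    def validate(self) -> None:
        if not (0.0 < self.baseline_survival <= 1.0):
            raise ValidationError(
                f"baseline_survival must lie in (0,1], got "
                f"{self.baseline_survival}")
        if self.horizon_years <= 0:
            raise ValidationError("horizon_years must be > 0")
        for term in self.coefficients:
            if term.transform not in _TRANSFORMS:
                raise ValidationError(
                    f"unknown transform '{term.transform}' for covariate "
                    f"'{term.covariate}'")


def load_coefficients(path: str | Path) -> list[CoefficientTerm]:
    """Read a coefficient CSV (covariate, transform, coefficient)."""
    df = pd.read_csv(path, comment="#")
    expected = {"covariate", "transform", "coefficient"}
    if set(df.columns) != expected:
        raise ConfigurationError(
            f"coefficient file {path} must have columns {sorted(expected)}")
    return [CoefficientTerm(r.covariate, r.transform, float(r.coefficient))
            for r in df.itertuples()]


def linear_predictor(profile, spec: RiskModelSpec) -> float:
    """Evaluate the (centred) linear predictor of ``spec`` at the cohort
    profile: the sum of coefficient * transform(covariate) over all terms.

    Prevalence fractions stand in for binary indicators, i.e. the cohort
    mean of each 0/1 covariate.
    """
    return float(sum(term.evaluate(profile) for term in spec.coefficients))


# The SMART equation is just a linear predictor with this module's generic
# machinery; the alias keeps the base-case entry point explicit.
smart_linear_predictor = linear_predictor


def horizon_risk(lp: float, spec: RiskModelSpec) -> float:
    """Risk over the equation's native horizon: 1 - S0 ** exp(lp)."""
    return 1.0 - spec.baseline_survival ** math.exp(lp)


def risk_to_cycle_prob(risk: float, risk_horizon: float,
                       cycle_len: float) -> float:
    """Convert a ``risk_horizon``-year risk to a per-cycle probability
    assuming a constant event rate over the horizon:

        p_cycle = 1 - (1 - risk) ** (cycle_len / risk_horizon)

    Monotone in both ``risk`` and ``cycle_len``; composing four quarterly
    probabilities reproduces the annual one exactly.
    """
    if risk >= 1.0:
        global _warned_degenerate_risk
        if not _warned_degenerate_risk:
            logger.warning("degenerate risk=1 passed to risk_to_cycle_prob "
                           "(further occurrences logged at DEBUG)")
            _warned_degenerate_risk = True
        else:
            logger.debug("degenerate risk=1 passed to risk_to_cycle_prob")
        return 1.0
    if risk < 0.0:
        raise ValidationError(f"risk must be >= 0, got {risk}")
    return 1.0 - (1.0 - risk) ** (cycle_len / risk_horizon)


@dataclass
class EventSplit:
    """Per-cycle probabilities of the four incident-event outcomes."""

    p_nonfatal_chd: float
    p_fatal_chd: float
    p_nonfatal_stroke: float
    p_fatal_stroke: float

    @property
    def total(self) -> float:
        return (self.p_nonfatal_chd + self.p_fatal_chd
                + self.p_nonfatal_stroke + self.p_fatal_stroke)

    @property
    def p_fatal(self) -> float:
        return self.p_fatal_chd + self.p_fatal_stroke

    def scaled(self, factor: float) -> "EventSplit":
        return EventSplit(self.p_nonfatal_chd * factor,
                          self.p_fatal_chd * factor,
                          self.p_nonfatal_stroke * factor,
                          self.p_fatal_stroke * factor)


def split_composite(p_event: float, epi: "EpidemiologyParams") -> EventSplit:
    """Split a composite event probability into typed fatal/nonfatal parts.

    The CHD share allocates the composite between CHD and stroke; each
    type's case-fatality fraction then allocates fatal vs nonfatal. The
    four components sum back to ``p_event`` exactly.
    """
    p_chd = p_event * epi.chd_share_of_events
    p_stroke = p_event - p_chd
    return EventSplit(
        p_nonfatal_chd=p_chd * (1.0 - epi.case_fatality_chd),
        p_fatal_chd=p_chd * epi.case_fatality_chd,
        p_nonfatal_stroke=p_stroke * (1.0 - epi.case_fatality_stroke),
        p_fatal_stroke=p_stroke * epi.case_fatality_stroke,
    )


class LifeTable:
    """Annual death probabilities by age and sex (columns ``age``,
    ``qx_male``, ``qx_female``), ages 0..max_age in steps of 1, with
    qx(max_age) = 1 as an absorbing cap."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._qm = frame["qx_male"].to_numpy(dtype=float)
        self._qf = frame["qx_female"].to_numpy(dtype=float)
        self._age0 = int(frame["age"].iloc[0])

    @property
    def max_age(self) -> int:
        return int(self.frame["age"].iloc[-1])

    def validate(self) -> None:
        ages = self.frame["age"].to_numpy()
        if not np.array_equal(np.diff(ages), np.ones(len(ages) - 1)):
            raise ValidationError("life-table ages must increase in steps of 1")
        for col in ("qx_male", "qx_female"):
            q = self.frame[col].to_numpy(dtype=float)
            if np.any(q < 0) or np.any(q > 1):
                raise ValidationError(f"{col} values must lie in [0,1]")
            if q[-1] != 1.0:
                raise ValidationError(f"{col} at max_age must be 1")

    def annual_qx(self, age: float, male_frac: float) -> float:
        """Sex-blended annual death probability at floor(age), clamped to
        the table's last row."""
        idx = min(max(int(math.floor(age)) - self._age0, 0), len(self._qm) - 1)
        return male_frac * self._qm[idx] + (1.0 - male_frac) * self._qf[idx]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        missing = {"age", "qx_male", "qx_female"} - set(df.columns)
        if missing:
            raise ConfigurationError(
                f"life table {path} missing columns {sorted(missing)}")
        table = cls(df[["age", "qx_male", "qx_female"]])
        table.validate()
        return table

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def noncv_death_prob(age: float, male_frac: float, table: LifeTable,
                     cycle_len: float) -> float:
    """Per-cycle non-CV death probability from the life table:
    the sex-blended annual qx converted as 1 - (1-qx) ** cycle_len."""
    qx = table.annual_qx(age, male_frac)
    return 1.0 - (1.0 - qx) ** cycle_len


def smart_cycle_probs(profile, spec: RiskModelSpec,
                      epi: "EpidemiologyParams",
                      cycle_len: float) -> EventSplit:
    """Composite-route per-cycle event split: SMART (or any single
    composite equation) risk over its native horizon, rescaled to the cycle
    length, then split by CHD share and case fatality."""
    lp = linear_predictor(profile, spec)
    p_cycle = risk_to_cycle_prob(horizon_risk(lp, spec),
                                 spec.horizon_years, cycle_len)
    return split_composite(p_cycle, epi)


def framingham_cycle_probs(profile, chd_spec: RiskModelSpec,
                           stroke_spec: RiskModelSpec,
                           epi: "EpidemiologyParams",
                           cycle_len: float) -> EventSplit:
    """Two-equation route: subsequent-CHD risk from the CHD equation,
    recurrent-stroke risk as the primary-stroke equation scaled by the
    recurrent-vs-primary relative risk (capped at 1). Each risk is
    converted to the cycle length with its own horizon, then split by its
    case-fatality fraction; no CHD-share re-weighting applies because the
    types come from separate equations.

    The two per-cycle probabilities are combined as competing risks: the
    probability of any event is 1 - (1-p_chd)(1-p_stroke) and is allocated
    to the two types in proportion to their marginal probabilities, which
    keeps the total below 1 even when both equations saturate at extreme
    ages.
    """
    if chd_spec is None or stroke_spec is None:
        raise ConfigurationError(
            "framingham route requires both a CHD and a stroke equation")
    chd_risk = horizon_risk(linear_predictor(profile, chd_spec), chd_spec)
    stroke_risk = min(
        horizon_risk(linear_predictor(profile, stroke_spec), stroke_spec)
        * epi.rr_recurrent_stroke, 1.0)
    p_chd = risk_to_cycle_prob(chd_risk, chd_spec.horizon_years, cycle_len)
    p_stroke = risk_to_cycle_prob(stroke_risk, stroke_spec.horizon_years,
                                  cycle_len)
    total = p_chd + p_stroke
    if total > 0.0:
        p_any = 1.0 - (1.0 - p_chd) * (1.0 - p_stroke)
        p_chd *= p_any / total
        p_stroke *= p_any / total
    return EventSplit(
        p_nonfatal_chd=p_chd * (1.0 - epi.case_fatality_chd),
        p_fatal_chd=p_chd * epi.case_fatality_chd,
        p_nonfatal_stroke=p_stroke * (1.0 - epi.case_fatality_stroke),
        p_fatal_stroke=p_stroke * epi.case_fatality_stroke,
    )
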