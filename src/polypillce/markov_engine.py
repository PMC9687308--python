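"""Cohort state-transition engine.

The drawn model has four health states (stable secondary prevention,
acute CHD, acute stroke, death split into CV and non-CV cause). Because
chronic utility and follow-up cost depend on *which* events a patient has
survived, the engine expands each alive state by an event-history tag
(post-CHD, post-stroke, or both), giving the 11-state space below. The
history tag is what lets the "lower of the two chronic utilities" rule and
history-specific follow-up costs be honoured in a memoryless chain.

Cycle structure: four 3-month cycles in the first model year, annual
cycles thereafter. State-time accruals (life-years, QALYs, drug and
follow-up costs) are half-cycle corrected with the trapezoid of start- and
end-of-cycle occupancy; incidence-based accruals (acute and fatal event
costs, event counts) are attributed at the transition and not corrected.
Costs and health outcomes are discounted yearly after the first year.

Competing risks within a cycle: non-CV death takes its full per-cycle
probability and the CV event split is scaled by (1 - m) so each transition
row remains stochastic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NumericError
from .parameters import (CohortProfile, ModelSettings, ParameterSet,
                         TreatmentEffect, effective_risk_factors)
from .risk_models import (EventSplit, framingham_cycle_probs,
                          noncv_death_prob, smart_cycle_probs)

__all__ = [
    "STATES", "N_STATES", "STABLE", "ACUTE_CHD", "ACUTE_STROKE",
    "DEAD_CV", "DEAD_NONCV", "ALIVE_STATES",
    "Cycle", "CycleInputs", "CohortTrace", "ArmResult",
    "build_cycle_schedule", "discount_factor", "transition_row",
    "build_transition_inputs", "apply_half_cycle_correction", "run_cohort",
]

# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------

HISTORIES = ("chd", "stroke", "both")

STABLE = {"chd": 0, "stroke": 1, "both": 2}
ACUTE_CHD = {"chd": 3, "stroke": 4, "both": 5}
ACUTE_STROKE = {"chd": 6, "stroke": 7, "both": 8}
DEAD_CV = 9
DEAD_NONCV = 10
N_STATES = 11

STATES = (
    "stable_chd", "stable_stroke", "stable_both",
    "acute_chd_chd", "acute_chd_stroke", "acute_chd_both",
    "acute_stroke_chd", "acute_stroke_stroke", "acute_stroke_both",
    "dead_cv", "dead_noncv",
)

ALIVE_STATES = tuple(range(9))

_HISTORY_OF = {**{v: h for h, v in STABLE.items()},
               **{v: h for h, v in ACUTE_CHD.items()},
               **{v: h for h, v in ACUTE_STROKE.items()}}


def _merge_history(history: str, event: str) -> str:
    """History after surviving a new event: chd+stroke (either order) and
    both+anything collapse to 'both'."""
    if history == "both" or history != event:
        return "both" if history != event else history
    return history


# ---------------------------------------------------------------------------
# Cycle schedule and discounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cycle:
    index: int
    t_start: float
    length: float


def build_cycle_schedule(settings: ModelSettings) -> list[Cycle]:
    """Quarterly cycles through year one, annual cycles thereafter; total
    duration equals the horizon."""
    cycles: list[Cycle] = []
    n_first = round(1.0 / settings.first_year_cycle_len)
    t = 0.0
    for i in range(n_first):
        cycles.append(Cycle(i, t, settings.first_year_cycle_len))
        t += settings.first_year_cycle_len
    i = n_first
    while t < settings.horizon_years - 1e-9:
        length = min(settings.later_cycle_len, settings.horizon_years - t)
        cycles.append(Cycle(i, t, length))
        t += length
        i += 1
    return cycles


def discount_factor(cycle_start_time: float, rate: float) -> float:
    """1.0 for cycles starting within the first model year, then
    (1+rate)^(-floor(t)): discounting applies yearly after year one."""
    if cycle_start_time < 1.0:
        return 1.0
    return (1.0 + rate) ** (-math.floor(cycle_start_time + 1e-12))


# ---------------------------------------------------------------------------
# Transition rows
# ---------------------------------------------------------------------------

def transition_row(state: int, split: EventSplit, noncv_m: float) -> np.ndarray:
    """One row of the transition matrix for an alive state.

    ``split`` must already be scaled by (1 - noncv_m) by the caller (see
    :func:`build_transition_inputs`); the residual after events and non-CV
    death returns to (or remains in) the stable state of the same history.
    """
    row = np.zeros(N_STATES)
    if state in (DEAD_CV, DEAD_NONCV):
        row[state] = 1.0
        return row
    h = _HISTORY_OF[state]
    row[ACUTE_CHD[_merge_history(h, "chd")]] += split.p_nonfatal_chd
    row[ACUTE_STROKE[_merge_history(h, "stroke")]] += split.p_nonfatal_stroke
    row[DEAD_CV] += split.p_fatal
    row[DEAD_NONCV] += noncv_m
    residual = 1.0 - split.total - noncv_m
    if residual < -1e-12:
        raise NumericError(
            f"transition probabilities over-allocated in state "
            f"{STATES[state]}: residual {residual:.3e}")
    row[STABLE[h]] += max(residual, 0.0)
    return row


@dataclass
class CycleInputs:
    """Everything needed to advance one cycle: the (already competing-risk
    scaled) event split, the non-CV death probability, and the full
    transition matrix built from :func:`transition_row`."""

    cycle: Cycle
    split: EventSplit
    noncv_m: float
    matrix: np.ndarray


def _arm_profile(params: ParameterSet, arm: TreatmentEffect) -> CohortProfile:
    return effective_risk_factors(params.profile, arm)


def _cycle_split(params: ParameterSet, profile: CohortProfile,
                 cycle_len: float) -> EventSplit:
    name = params.settings.risk_model_name
    if name == "framingham":
        try:
            chd = params.risk_models["framingham_chd"]
            stroke = params.risk_models["framingham_stroke"]
        except KeyError as exc:
            raise ConfigurationError(
                f"framingham route requires risk model '{exc.args[0]}'")
        return framingham_cycle_probs(profile, chd, stroke, params.epi,
                                      cycle_len)
    try:
        spec = params.risk_models[name]
    except KeyError:
        raise ConfigurationError(f"unknown risk model '{name}'") from None
    return smart_cycle_probs(profile, spec, params.epi, cycle_len)


def build_transition_inputs(params: ParameterSet,
                            arm: TreatmentEffect) -> list[CycleInputs]:
    """Precompute per-cycle transition data for one arm.

    Risk is recomputed every cycle with age and years-since-first-event
    advanced by elapsed model time; the remaining covariates stay at their
    arm-adjusted baseline values. The same rows drive both the cohort run
    and any walker-level simulation, so the two are comparable
    transition-for-transition.
    """
    base = _arm_profile(params, arm)
    out: list[CycleInputs] = []
    for cyc in build_cycle_schedule(params.settings):
        profile_t = dataclasses.replace(
            base,
            starting_age=base.starting_age + cyc.t_start,
            years_since_first_event=(base.years_since_first_event
                                     + cyc.t_start),
        )
        m = noncv_death_prob(profile_t.starting_age, profile_t.male_frac,
                             params.epi.life_table, cyc.length)
        split = _cycle_split(params, profile_t, cyc.length).scaled(1.0 - m)
        matrix = np.vstack([transition_row(s, split, m)
                            for s in range(N_STATES)])
        out.append(CycleInputs(cyc, split, m, matrix))
    return out


# ---------------------------------------------------------------------------
# Trace and results
# ---------------------------------------------------------------------------

_FLOW_COLS = ("inc_nonfatal_chd", "inc_fatal_chd", "inc_nonfatal_stroke",
              "inc_fatal_stroke", "inc_noncv_death")

_ACCRUAL_COLS = ("ly", "qaly", "drug_cost", "followup_cost",
                 "acute_event_cost", "cycle_cost",
                 "disc_ly", "disc_qaly", "disc_drug_cost",
                 "disc_followup_cost", "disc_acute_event_cost",
                 "disc_cycle_cost")


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run (per-patient scale: occupancy
    fractions and expected accruals per individual).

    ``occupancy`` holds start-of-cycle occupancy for every cycle plus the
    end-of-horizon row (shape ``(n_cycles + 1, 11)``). ``flows`` are
    expected incident transitions per cycle. Accrual columns are filled by
    :func:`apply_half_cycle_correction` (trapezoidal) or its uncorrected
    counterpart.
    """

    schedule: list[Cycle]
    occupancy: np.ndarray
    flows: pd.DataFrame
    utilities: np.ndarray
    followup_costs: np.ndarray
    annual_drug_cost: float
    acute_cost_vector: np.ndarray  # per _FLOW_COLS[:4]
    discount_rate: float
    accruals: pd.DataFrame | None = None
    half_cycle_corrected: bool = False

    @property
    def ages(self) -> np.ndarray:
        return np.array([c.t_start for c in self.schedule])

    def check_conservation(self, tol: float = 1e-10) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol) or np.any(self.occupancy < -tol):
            worst = int(np.argmax(np.abs(sums - 1.0)))
            raise NumericError(
                f"occupancy not conserved at cycle {worst}: sum {sums[worst]!r}")

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: metadata, state occupancies, flows, accruals."""
        meta = pd.DataFrame({
            "cycle": [c.index for c in self.schedule],
            "t_start": [c.t_start for c in self.schedule],
            "length": [c.length for c in self.schedule],
        })
        occ = pd.DataFrame(self.occupancy[:-1], columns=STATES)
        parts = [meta, occ, self.flows.reset_index(drop=True)]
        if self.accruals is not None:
            parts.append(self.accruals.reset_index(drop=True))
        return pd.concat(parts, axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _fill_accruals(trace: CohortTrace, corrected: bool) -> CohortTrace:
    """Compute per-cycle accruals from occupancy and flows.

    ``corrected`` selects trapezoidal (average of start/end occupancy) vs
    start-of-cycle state-time attribution. Incidence-based costs are never
    corrected.
    """
    n = len(trace.schedule)
    occ_start = trace.occupancy[:-1]
    occ_end = trace.occupancy[1:]
    occ_eff = 0.5 * (occ_start + occ_end) if corrected else occ_start

    lengths = np.array([c.length for c in trace.schedule])
    dfs = np.array([discount_factor(c.t_start, trace.discount_rate)
                    for c in trace.schedule])

    alive = occ_eff[:, :9].sum(axis=1)
    ly = alive * lengths
    qaly = occ_eff @ trace.utilities * lengths
    drug = trace.annual_drug_cost * alive * lengths
    followup = occ_eff @ trace.followup_costs * lengths
    acute = trace.flows[list(_FLOW_COLS[:4])].to_numpy() @ trace.acute_cost_vector
    cycle_cost = drug + followup + acute

    data = {
        "ly": ly, "qaly": qaly, "drug_cost": drug,
        "followup_cost": followup, "acute_event_cost": acute,
        "cycle_cost": cycle_cost,
        "disc_ly": ly * dfs, "disc_qaly": qaly * dfs,
        "disc_drug_cost": drug * dfs, "disc_followup_cost": followup * dfs,
        "disc_acute_event_cost": acute * dfs,
        "disc_cycle_cost": cycle_cost * dfs,
    }
    if not np.all(np.isfinite(cycle_cost)):
        bad = int(np.argmax(~np.isfinite(cycle_cost)))
        raise NumericError(f"non-finite accumulator at cycle {bad}")
    trace.accruals = pd.DataFrame(data, columns=list(_ACCRUAL_COLS))
    trace.half_cycle_corrected = corrected
    return trace


def apply_half_cycle_correction(trace: CohortTrace) -> CohortTrace:
    """Recompute state-time accruals with the trapezoid of start- and
    end-of-cycle occupancy. Exact for linearly-varying occupancy; the
    identity for constant occupancy. Incidence-based (acute/fatal event)
    costs are left untouched."""
    return _fill_accruals(trace, corrected=True)


@dataclass
class ArmResult:
    """Totals for one arm, scaled to the cohort size.

    Costs, LY and QALY are discounted; event counts are undiscounted
    expected counts over the horizon.
    """

    arm_name: str
    total_cost: float
    drug_cost: float
    acute_event_cost: float
    followup_cost: float
    ly: float
    qaly: float
    ly_undiscounted: float
    qaly_undiscounted: float
    n_chd_events: float
    n_strokes: float
    n_cv_deaths: float
    n_noncv_deaths: float
    cohort_size: int

    def validate(self) -> None:
        parts = self.drug_cost + self.acute_event_cost + self.followup_cost
        if abs(parts - self.total_cost) > 1e-6:
            raise NumericError("cost components do not sum to total cost")
        if self.qaly > self.ly + 1e-9:
            raise NumericError("QALY exceeded LY")


def _utility_vector(params: ParameterSet) -> np.ndarray:
    u = params.utilities
    vec = np.zeros(N_STATES)
    vec[STABLE["chd"]] = u.chronic_chd
    vec[STABLE["stroke"]] = u.chronic_stroke
    vec[STABLE["both"]] = min(u.chronic_chd, u.chronic_stroke)
    for s in ACUTE_CHD.values():
        vec[s] = u.acute_chd
    for s in ACUTE_STROKE.values():
        vec[s] = u.acute_stroke
    vec[DEAD_CV] = vec[DEAD_NONCV] = u.death
    return vec


def _followup_vector(params: ParameterSet) -> np.ndarray:
    """Annual follow-up cost by state: stable states only (acute-event
    costs are all-inclusive for the acute cycle), with both-history paying
    the higher of the two annual costs."""
    c = params.costs
    vec = np.zeros(N_STATES)
    vec[STABLE["chd"]] = c.annual_post_chd
    vec[STABLE["stroke"]] = c.annual_post_stroke
    vec[STABLE["both"]] = max(c.annual_post_chd, c.annual_post_stroke)
    return vec


def run_cohort(params: ParameterSet,
               arm: TreatmentEffect) -> tuple[CohortTrace, ArmResult]:
    """Run the cohort through the horizon for one arm.

    The cohort starts fully in the stable states, split by the post-CHD /
    post-stroke history weights. Each cycle advances occupancy by the
    transition matrix, records expected incident events, and accrues
    costs, life-years and QALYs (half-cycle corrected and discounted per
    the settings). Totals are scaled by the cohort size.
    """
    inputs = build_transition_inputs(params, arm)
    n = len(inputs)
    occ = np.zeros((n + 1, N_STATES))
    occ[0, STABLE["chd"]] = params.profile.post_chd_weight
    occ[0, STABLE["stroke"]] = params.profile.post_stroke_weight

    flows = np.zeros((n, len(_FLOW_COLS)))
    for i, ci in enumerate(inputs):
        alive_mass = occ[i, :9].sum()
        s = ci.split
        flows[i] = (alive_mass * s.p_nonfatal_chd,
                    alive_mass * s.p_fatal_chd,
                    alive_mass * s.p_nonfatal_stroke,
                    alive_mass * s.p_fatal_stroke,
                    alive_mass * ci.noncv_m)
        occ[i + 1] = occ[i] @ ci.matrix

    c = params.costs
    trace = CohortTrace(
        schedule=[ci.cycle for ci in inputs],
        occupancy=occ,
        flows=pd.DataFrame(flows, columns=list(_FLOW_COLS)),
        utilities=_utility_vector(params),
        followup_costs=_followup_vector(params),
        annual_drug_cost=arm.annual_drug_cost,
        acute_cost_vector=np.array([c.acute_chd_nonfatal, c.acute_chd_fatal,
                                    c.acute_stroke_nonfatal,
                                    c.acute_stroke_fatal]),
        discount_rate=params.settings.discount_rate,
    )
    trace.check_conservation()
    trace = _fill_accruals(trace,
                           corrected=params.settings.half_cycle_correction)

    acc = trace.accruals
    size = params.profile.cohort_size
    fl = trace.flows
    result = ArmResult(
        arm_name=arm.arm_name,
        total_cost=float(acc["disc_cycle_cost"].sum()) * size,
        drug_cost=float(acc["disc_drug_cost"].sum()) * size,
        acute_event_cost=float(acc["disc_acute_event_cost"].sum()) * size,
        followup_cost=float(acc["disc_followup_cost"].sum()) * size,
        ly=float(acc["disc_ly"].sum()) * size,
        qaly=float(acc["disc_qaly"].sum()) * size,
        ly_undiscounted=float(acc["ly"].sum()) * size,
        qaly_undiscounted=float(acc["qaly"].sum()) * size,
        n_chd_events=float(fl["inc_nonfatal_chd"].sum()) * size,
        n_strokes=float(fl["inc_nonfatal_stroke"].sum()) * size,
        n_cv_deaths=float((fl["inc_fatal_chd"]
                           + fl["inc_fatal_stroke"]).sum()) * size,
        n_noncv_deaths=float(fl["inc_noncv_death"].sum()) * size,
        cohort_size=size,
    )
    result.validate()
    return trace, result
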