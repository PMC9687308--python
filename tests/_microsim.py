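"""Walker-level Monte-Carlo oracle for the cohort engine.

Simulates individual random walks through exactly the same per-cycle
transition matrices the cohort run uses, accruing per-walker discounted
life-years and QALYs with the same trapezoidal attribution, so the cohort
trace's expectations can be checked against empirical means within
Monte-Carlo error. Test-side oracle only; not part of the package.
"""

from dataclasses import dataclass

import numpy as np

from polypillce.markov_engine import (DEAD_CV, N_STATES, STABLE,
                                      build_transition_inputs,
                                      discount_factor, _utility_vector)


@dataclass
class MicrosimSummary:
    ly: float
    ly_se: float
    qaly: float
    qaly_se: float
    nonfatal_chd: float
    nonfatal_chd_se: float
    nonfatal_stroke: float
    nonfatal_stroke_se: float
    cv_deaths: float
    cv_deaths_se: float


def microsimulate(params, arm, n_walkers: int, seed: int) -> MicrosimSummary:
    rng = np.random.default_rng(seed)
    inputs = build_transition_inputs(params, arm)
    u = _utility_vector(params)
    rate = params.settings.discount_rate

    w = params.profile.post_chd_weight
    states = rng.choice([STABLE["chd"], STABLE["stroke"]], size=n_walkers,
                        p=[w, 1.0 - w])
    ly = np.zeros(n_walkers)
    qaly = np.zeros(n_walkers)
    nf_chd = np.zeros(n_walkers)
    nf_stroke = np.zeros(n_walkers)
    cv_dead = np.zeros(n_walkers)

    for ci in inputs:
        length = ci.cycle.length
        df = discount_factor(ci.cycle.t_start, rate)
        new = np.empty_like(states)
        for s in np.unique(states):
            idx = np.flatnonzero(states == s)
            new[idx] = rng.choice(N_STATES, size=idx.size, p=ci.matrix[s])
        alive0 = (states < 9).astype(float)
        alive1 = (new < 9).astype(float)
        ly += 0.5 * (alive0 + alive1) * length * df
        qaly += 0.5 * (u[states] + u[new]) * length * df
        nf_chd += ((new >= 3) & (new <= 5)).astype(float)
        nf_stroke += ((new >= 6) & (new <= 8)).astype(float)
        cv_dead += ((new == DEAD_CV) & (states != DEAD_CV)).astype(float)
        states = new

    def mean_se(x):
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n_walkers))

    vals = {}
    for name, arr in (("ly", ly), ("qaly", qaly), ("nonfatal_chd", nf_chd),
                      ("nonfatal_stroke", nf_stroke), ("cv_deaths", cv_dead)):
        m, se = mean_se(arr)
        vals[name] = m
        vals[name + "_se"] = se
    return MicrosimSummary(**vals)
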