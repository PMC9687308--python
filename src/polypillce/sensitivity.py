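"""Deterministic (one-way) and probabilistic sensitivity analysis.

OWSA sweeps each parameter alone to 0.8x and 1.2x its base value with
everything else fixed, recording the effect on the ICER, incremental cost
and incremental QALY; entries are ranked by spread for tornado display.

The PSA jointly resamples all uncertain inputs: normal for continuous
population characteristics and treatment-effect deltas, beta
(moment-matched) for proportions, utilities and baseline survival, gamma
for costs, lognormal for the recurrent-stroke relative risk, and normal
for risk-equation coefficients (the centring offset is held fixed). In
the absence of published variability, every standard error defaults to
20% of the mean; per-parameter overrides are accepted. Draws are
truncated to valid ranges. One master seed spawns per-iteration
substreams, so the first 1000 iterations of a 5000-iteration run are
identical to a 1000-iteration run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import CEResult, compare
from .exceptions import ConfigurationError
from .markov_engine import run_cohort
from .parameters import ParameterSet, get_param, set_param

logger = logging.getLogger(__name__)

__all__ = [
    "TornadoEntry", "PSADraw", "CEACPoint", "PSAResult",
    "default_swept_parameters", "run_owsa",
    "beta_params_from_moments", "sample_psa_params", "run_psa",
    "ceac", "prob_cost_effective", "prob_cost_saving",
]

OWSA_LOW = 0.8
OWSA_HIGH = 1.2


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


_POPULATION_SCALARS = (
    "population.starting_age", "population.male_frac",
    "population.smoker_frac", "population.diabetes_frac",
    "population.afib_frac", "population.lvh_frac", "population.sbp",
    "population.tc", "population.hdl", "population.hscrp",
    "population.egfr", "population.aaa_history_frac",
    "population.pad_history_frac", "population.years_since_first_event",
    "population.post_chd_weight",
)

_ARM_SCALARS = (
    "arms.intervention.sbp_delta", "arms.intervention.tc_delta",
    "arms.intervention.hdl_delta", "arms.intervention.annual_drug_cost",
    "arms.comparator.annual_drug_cost",
)

_COST_SCALARS = (
    "costs.acute_chd_nonfatal", "costs.acute_chd_fatal",
    "costs.acute_stroke_nonfatal", "costs.acute_stroke_fatal",
    "costs.annual_post_chd", "costs.annual_post_stroke",
)

_UTILITY_SCALARS = (
    "utilities.chronic_chd", "utilities.chronic_stroke",
    "utilities.acute_chd", "utilities.acute_stroke",
)

_EPI_SCALARS = (
    "epidemiology.chd_share_of_events", "epidemiology.case_fatality_chd",
    "epidemiology.case_fatality_stroke", "epidemiology.rr_recurrent_stroke",
)


def default_swept_parameters(params: ParameterSet) -> list[str]:
    """Every scalar model input: profile, arm effects and drug costs,
    costs, utilities, epidemiology, the discount rate, and the active
    risk equation's baseline survival."""
    swept = list(_POPULATION_SCALARS + _ARM_SCALARS + _COST_SCALARS
                 + _UTILITY_SCALARS + _EPI_SCALARS)
    swept.append("settings.discount_rate")
    name = params.settings.risk_model_name
    if name == "framingham":
        swept += ["risk_models.framingham_chd.baseline_survival",
                  "risk_models.framingham_stroke.baseline_survival"]
    else:
        swept.append(f"risk_models.{name}.baseline_survival")
    return swept


def _run_comparison(params: ParameterSet) -> CEResult:
    _, inter = run_cohort(params, params.intervention)
    _, comp = run_cohort(params, params.comparator)
    return compare(inter, comp, params.settings.wtp_threshold)


def run_owsa(params: ParameterSet,
             swept: list[str] | None = None
             ) -> dict[str, list[TornadoEntry]]:
    """One-way sweep of each parameter to 0.8x / 1.2x base.

    Returns tornado lists keyed by outcome (``icer``, ``icur``,
    ``delta_cost``, ``delta_qaly``), each sorted by descending spread.
    Invariants are intentionally not re-validated on the excursions, so
    mechanical bounds crossings (e.g. a utility pushed past 1) run as-is.
    """
    swept = swept if swept is not None else default_swept_parameters(params)
    per_param: list[tuple[str, float, float, CEResult, CEResult]] = []
    for path in swept:
        base = get_param(params, path)
        if not isinstance(base, (int, float)) or isinstance(base, bool):
            raise ConfigurationError(
                f"swept parameter '{path}' is not a scalar")
        lo, hi = base * OWSA_LOW, base * OWSA_HIGH
        res_lo = _run_comparison(set_param(params, path, lo))
        res_hi = _run_comparison(set_param(params, path, hi))
        per_param.append((path, lo, hi, res_lo, res_hi))

    def extract(attr: str) -> list[TornadoEntry]:
        entries = [TornadoEntry(p, lo, hi, getattr(rl, attr),
                                getattr(rh, attr))
                   for p, lo, hi, rl, rh in per_param]
        return sorted(entries, key=lambda e: (-e.spread
                                              if math.isfinite(e.spread)
                                              else math.inf), )

    out = {name: extract(attr)
           for name, attr in (("icer", "icer"), ("icur", "icur"),
                              ("delta_cost", "delta_cost"),
                              ("delta_qaly", "delta_qaly"))}
    return out


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": e.parameter, "low": e.low, "high": e.high,
          "outcome_low": e.outcome_low, "outcome_high": e.outcome_high,
          "spread": e.spread} for e in entries])


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched beta shape parameters; raises if infeasible
    (variance >= mean*(1-mean))."""
    v = sd * sd
    bound = mean * (1.0 - mean)
    if v >= bound:
        raise ValueError("beta moment matching infeasible")
    k = bound / v - 1.0
    return mean * k, (1.0 - mean) * k


def _draw_normal(rng, mean, sd, lo=None, hi=None):
    x = rng.normal(mean, sd)
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x


def _draw_beta(rng, mean, sd, label=""):
    if sd == 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    try:
        a, b = beta_params_from_moments(mean, sd)
    except ValueError:
        logger.warning("beta moment matching infeasible for %s "
                       "(mean %.4g, sd %.4g); truncated normal used",
                       label, mean, sd)
        return _draw_normal(rng, mean, sd, 0.0, 1.0)
    return rng.beta(a, b)


def _draw_gamma(rng, mean, sd):
    if sd == 0 or mean == 0:
        return mean
    v = sd * sd
    return rng.gamma(mean * mean / v, v / mean)


def _draw_lognormal(rng, mean, sd):
    if sd == 0:
        return mean
    sigma2 = math.log(1.0 + (sd * sd) / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2))


_NORMAL_POSITIVE = (
    "population.starting_age", "population.sbp", "population.tc",
    "population.hdl", "population.hscrp", "population.egfr",
)
_NORMAL_FREE = (
    "population.years_since_first_event",
    "arms.intervention.sbp_delta", "arms.intervention.tc_delta",
    "arms.intervention.hdl_delta",
    "arms.comparator.sbp_delta", "arms.comparator.tc_delta",
    "arms.comparator.hdl_delta",
)
_BETA_PATHS = (
    "population.male_frac", "population.smoker_frac",
    "population.diabetes_frac", "population.afib_frac",
    "population.lvh_frac", "population.aaa_history_frac",
    "population.pad_history_frac", "population.post_chd_weight",
    "epidemiology.chd_share_of_events", "epidemiology.case_fatality_chd",
    "epidemiology.case_fatality_stroke",
    "utilities.chronic_chd", "utilities.chronic_stroke",
    "utilities.acute_chd", "utilities.acute_stroke",
)
_GAMMA_PATHS = (
    "costs.acute_chd_nonfatal", "costs.acute_chd_fatal",
    "costs.acute_stroke_nonfatal", "costs.acute_stroke_fatal",
    "costs.annual_post_chd", "costs.annual_post_stroke",
    "arms.intervention.annual_drug_cost", "arms.comparator.annual_drug_cost",
)
_LOGNORMAL_PATHS = ("epidemiology.rr_recurrent_stroke",)


def _active_models(params: ParameterSet) -> list[str]:
    name = params.settings.risk_model_name
    if name == "framingham":
        return ["framingham_chd", "framingham_stroke"]
    return [name]


def sample_psa_params(params: ParameterSet,
                      rng_seed: int | np.random.Generator,
                      se_scale: float = 0.2,
                      se_overrides: dict[str, float] | None = None
                      ) -> ParameterSet:
    """Draw one PSA parameter set around the base values.

    Each stochastic input is drawn from its assigned family with mean
    equal to the base value and standard error ``se_scale`` times the
    base (absolute value for signed inputs); ``se_overrides`` maps a
    dotted path to a per-parameter scale. With ``se_scale=0`` the base
    set is returned unchanged. Deterministic for a fixed seed.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    overrides = se_overrides or {}

    def scale_for(path: str) -> float:
        return overrides.get(path, se_scale)

    new = params.copy()
    if se_scale == 0 and not overrides:
        return new

    def sample_path(path: str, family: str, **kw):
        nonlocal new
        mean = get_param(params, path)
        sd = scale_for(path) * abs(mean)
        if sd == 0:
            return
        if family == "normal":
            val = _draw_normal(rng, mean, sd, **kw)
        elif family == "beta":
            val = _draw_beta(rng, mean, sd, label=path)
        elif family == "gamma":
            val = _draw_gamma(rng, mean, sd)
        else:
            val = _draw_lognormal(rng, mean, sd)
        new = set_param(new, path, val)

    for path in _NORMAL_POSITIVE:
        sample_path(path, "normal", lo=1e-6)
    for path in _NORMAL_FREE:
        sample_path(path, "normal")
    for path in _BETA_PATHS:
        sample_path(path, "beta")
    for path in _GAMMA_PATHS:
        sample_path(path, "gamma")
    for path in _LOGNORMAL_PATHS:
        sample_path(path, "lognormal")

    # acute utilities stay below their chronic counterparts (truncation to
    # the valid range rather than re-draw)
    u = new.utilities
    u.acute_chd = min(u.acute_chd, u.chronic_chd)
    u.acute_stroke = min(u.acute_stroke, u.chronic_stroke)

    # risk-equation uncertainty: beta on baseline survival, normal on each
    # coefficient; the centring offset is calibration, not estimation.
    for model in _active_models(new):
        spec = new.risk_models[model]
        path = f"risk_models.{model}.baseline_survival"
        sd = scale_for(path) * spec.baseline_survival
        if sd > 0:
            spec.baseline_survival = float(
                np.clip(_draw_beta(rng, spec.baseline_survival, sd,
                                   label=path), 1e-9, 1.0))
        coeff_scale = scale_for(f"risk_models.{model}.coefficients")
        for term in spec.coefficients:
            if term.transform == "offset" or term.coefficient == 0:
                continue
            term.coefficient = _draw_normal(
                rng, term.coefficient, coeff_scale * abs(term.coefficient))
    return new


@dataclass
class PSADraw:
    """One Monte-Carlo iteration's incremental outcomes."""

    iteration: int
    delta_cost: float
    delta_ly: float
    delta_qaly: float


@dataclass
class PSAResult:
    """PSA cloud plus its summaries.

    ``mean_icur`` is the ratio of means mean(dcost)/mean(dQALY), the
    conventional single "average ICUR" of a PSA cloud; the mean of
    per-draw ratios is exported alongside for completeness.
    """

    draws: list[PSADraw]
    n_failed: int = 0

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"iteration": d.iteration, "delta_cost": d.delta_cost,
              "delta_ly": d.delta_ly, "delta_qaly": d.delta_qaly}
             for d in self.draws])

    @property
    def mean_delta_cost(self) -> float:
        return float(np.mean([d.delta_cost for d in self.draws]))

    @property
    def mean_delta_qaly(self) -> float:
        return float(np.mean([d.delta_qaly for d in self.draws]))

    @property
    def mean_icur(self) -> float:
        dq = self.mean_delta_qaly
        return self.mean_delta_cost / dq if dq != 0 else math.nan

    @property
    def mean_of_ratios(self) -> float:
        ratios = [d.delta_cost / d.delta_qaly for d in self.draws
                  if d.delta_qaly != 0]
        return float(np.mean(ratios)) if ratios else math.nan

    def prob_cost_effective(self, wtp: float) -> float:
        return prob_cost_effective(self.draws, wtp)

    def prob_cost_saving(self) -> float:
        return prob_cost_saving(self.draws)

    def ceac(self, wtp_grid=None) -> list["CEACPoint"]:
        return ceac(self.draws, wtp_grid)

    def plot_scatter(self, ax=None):
        """Incremental cost vs incremental QALY cloud."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        ax.scatter(f["delta_qaly"], f["delta_cost"], s=6, alpha=0.4)
        ax.axhline(0, color="grey", lw=0.8)
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (EUR)")
        return ax

    def plot_ceac(self, wtp_grid=None, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        pts = self.ceac(wtp_grid)
        ax.plot([p.wtp for p in pts], [p.prob_cost_effective for p in pts])
        ax.set_xlabel("Willingness-to-pay (EUR/QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(0, 1)
        return ax


def run_psa(params: ParameterSet, n_iter: int, seed: int,
            se_scale: float = 0.2,
            se_overrides: dict[str, float] | None = None) -> PSAResult:
    """Monte-Carlo simulation: ``n_iter`` sampled parameter sets, each run
    through both arms. Iterations use independent substreams spawned from
    the master seed, so a shorter run is a prefix of a longer one with the
    same seed. Numerically failing iterations are excluded with a logged
    count."""
    children = np.random.SeedSequence(seed).spawn(n_iter)
    draws: list[PSADraw] = []
    n_failed = 0
    for i in range(n_iter):
        rng = np.random.default_rng(children[i])
        try:
            sampled = sample_psa_params(params, rng, se_scale, se_overrides)
            res = _run_comparison(sampled)
        except Exception:  # noqa: BLE001 - any failed draw is excluded
            n_failed += 1
            logger.exception("PSA iteration %d failed; excluded", i)
            continue
        draws.append(PSADraw(i, res.delta_cost, res.delta_ly, res.delta_qaly))
    if n_failed:
        logger.warning("%d of %d PSA iterations failed", n_failed, n_iter)
    return PSAResult(draws=draws, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Acceptability
# ---------------------------------------------------------------------------

@dataclass
class CEACPoint:
    wtp: float
    prob_cost_effective: float


DEFAULT_WTP_GRID = np.arange(0, 100_001, 1000)


def prob_cost_effective(draws: list[PSADraw], wtp: float) -> float:
    """Fraction of draws with positive net monetary benefit at ``wtp``."""
    if not draws:
        raise ValueError("empty draw set")
    hits = sum(1 for d in draws if wtp * d.delta_qaly - d.delta_cost > 0)
    return hits / len(draws)


def prob_cost_saving(draws: list[PSADraw]) -> float:
    """Fraction of draws where the intervention is dominant (cheaper and
    more effective)."""
    if not draws:
        raise ValueError("empty draw set")
    hits = sum(1 for d in draws if d.delta_cost < 0 and d.delta_qaly > 0)
    return hits / len(draws)


def ceac(draws: list[PSADraw], wtp_grid=None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay
    grid (default 0..100 000 EUR/QALY in steps of 1000)."""
    grid = DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid
    return [CEACPoint(float(w), prob_cost_effective(draws, float(w)))
            for w in grid]
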