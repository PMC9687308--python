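"""Model/Results front-end over the cohort engine.

`MarkovCostUtility` bundles a validated parameter set; ``fit()`` runs both
treatment arms through the Markov cohort engine and returns a
:class:`CostUtilityResults` carrying the arm totals, the incremental
comparison, traces for audit, and entry points for uncertainty analysis
(one-way sweeps, probabilistic sensitivity analysis) and scenario grids.

    >>> model = MarkovCostUtility.from_yaml()        # packaged base case
    >>> res = model.fit()
    >>> print(res.summary())
    >>> psa = res.run_psa(n_iter=1000, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .economics import CEResult, compare
from .markov_engine import ArmResult, CohortTrace, run_cohort
from .parameters import (ParameterSet, load_parameters,
                         packaged_basecase_path)
from .scenarios import (ScenarioResult, ScenarioSpec, results_table,
                        run_scenarios)
from .sensitivity import PSAResult, TornadoEntry, run_owsa, run_psa

__all__ = ["MarkovCostUtility", "CostUtilityResults"]


class MarkovCostUtility:
    """Markov cohort cost-utility model for two treatment strategies."""

    def __init__(self, params: ParameterSet):
        params.validate()
        self.params = params

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "MarkovCostUtility":
        """Build from a parameter file; defaults to the packaged base case."""
        return cls(load_parameters(path or packaged_basecase_path()))

    def fit(self) -> "CostUtilityResults":
        """Run both arms deterministically and compare them."""
        trace_i, res_i = run_cohort(self.params, self.params.intervention)
        trace_c, res_c = run_cohort(self.params, self.params.comparator)
        ce = compare(res_i, res_c, self.params.settings.wtp_threshold)
        return CostUtilityResults(self, res_i, res_c, trace_i, trace_c, ce)


@dataclass
class CostUtilityResults:
    """Deterministic results of one fitted comparison; uncertainty and
    scenario analyses hang off this object."""

    model: MarkovCostUtility
    intervention: ArmResult
    comparator: ArmResult
    intervention_trace: CohortTrace
    comparator_trace: CohortTrace
    ce: CEResult

    def summary(self) -> str:
        """Plain-text summary table of arm totals and incremental results."""
        p = self.model.params
        rows = []
        for label, i, c in (
            ("Total cost (EUR)", self.intervention.total_cost,
             self.comparator.total_cost),
            ("  drug cost", self.intervention.drug_cost,
             self.comparator.drug_cost),
            ("  acute event cost", self.intervention.acute_event_cost,
             self.comparator.acute_event_cost),
            ("  follow-up cost", self.intervention.followup_cost,
             self.comparator.followup_cost),
            ("Life-years (disc.)", self.intervention.ly, self.comparator.ly),
            ("QALYs (disc.)", self.intervention.qaly, self.comparator.qaly),
            ("Subsequent CHD events", self.intervention.n_chd_events,
             self.comparator.n_chd_events),
            ("Recurrent strokes", self.intervention.n_strokes,
             self.comparator.n_strokes),
            ("CV deaths", self.intervention.n_cv_deaths,
             self.comparator.n_cv_deaths),
        ):
            rows.append((label, i, c, i - c))
        df = pd.DataFrame(rows, columns=[
            "", self.intervention.arm_name, self.comparator.arm_name,
            "incremental"]).set_index("")
        lines = [
            "Markov cohort cost-utility comparison "
            f"(cohort of {p.profile.cohort_size}, "
            f"{p.settings.horizon_years}-year horizon, "
            f"{p.settings.discount_rate:.0%} discount)",
            df.round(2).to_string(),
            "",
            f"ICER: {self._fmt_ratio(self.ce.icer)} EUR/LY gained",
            f"ICUR: {self._fmt_ratio(self.ce.icur)} EUR/QALY gained",
            f"Dominance: {self.ce.dominance}",
            f"NMB at {self.ce.wtp:,.0f} EUR/QALY: {self.ce.nmb:,.0f} EUR",
        ]
        return "\n".join(lines)

    @staticmethod
    def _fmt_ratio(x: float) -> str:
        return f"{round(x):,}" if x == x else "n/a (see dominance)"

    # ---- uncertainty / scenarios -------------------------------------

    def run_psa(self, n_iter: int = 1000, seed: int = 0,
                se_scale: float = 0.2) -> PSAResult:
        return run_psa(self.model.params, n_iter, seed, se_scale)

    def run_owsa(self, swept: list[str] | None = None
                 ) -> dict[str, list[TornadoEntry]]:
        return run_owsa(self.model.params, swept)

    def run_scenarios(self, specs: list[ScenarioSpec] | None = None,
                      psa_iterations: int = 0,
                      seed: int = 0) -> list[ScenarioResult]:
        return run_scenarios(self.model.params, specs, psa_iterations, seed)

    def scenario_table(self, **kwargs) -> pd.DataFrame:
        return results_table(self.run_scenarios(**kwargs))
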