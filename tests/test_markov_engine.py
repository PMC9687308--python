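"""Cohort engine: schedule, transition rows, accrual rules, discounting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from polypillce.exceptions import NumericError
from polypillce.markov_engine import (ACUTE_CHD, ACUTE_STROKE, DEAD_CV,
                                      DEAD_NONCV, N_STATES, STABLE,
                                      CohortTrace, Cycle,
                                      apply_half_cycle_correction,
                                      build_cycle_schedule, discount_factor,
                                      run_cohort, transition_row)
from polypillce.parameters import set_param
from polypillce.risk_models import EventSplit


class TestCycleSchedule:
    @pytest.mark.parametrize("horizon,n_cycles", [(32, 35), (2, 5), (1, 4)])
    def test_quarterly_then_annual(self, base_params, horizon, n_cycles):
        settings = dataclasses.replace(base_params.settings,
                                       horizon_years=horizon)
        sched = build_cycle_schedule(settings)
        assert len(sched) == n_cycles
        assert [c.length for c in sched[:4]] == [0.25] * 4
        assert sum(c.length for c in sched) == pytest.approx(horizon)
        assert sched[0].t_start == 0.0


class TestDiscounting:
    def test_first_year_undiscounted(self):
        assert discount_factor(0.0, 0.04) == 1.0
        assert discount_factor(0.5, 0.04) == 1.0

    def test_yearly_after_first_year(self):
        assert discount_factor(1.0, 0.04) == pytest.approx(1 / 1.04)
        assert discount_factor(10.0, 0.04) == pytest.approx(1.04 ** -10)

    def test_zero_rate_never_discounts(self):
        for t in (0.0, 1.0, 17.0):
            assert discount_factor(t, 0.0) == 1.0


class TestTransitionRow:
    def test_no_risk_is_identity(self):
        row = transition_row(STABLE["chd"], EventSplit(0, 0, 0, 0), 0.0)
        expected = np.zeros(N_STATES)
        expected[STABLE["chd"]] = 1.0
        np.testing.assert_allclose(row, expected)

    def test_dead_states_absorbing(self):
        for s in (DEAD_CV, DEAD_NONCV):
            row = transition_row(s, EventSplit(0.1, 0.1, 0.1, 0.1), 0.5)
            assert row[s] == 1.0 and row.sum() == 1.0

    def test_hand_built_row(self):
        """Composite 0.1 split (0.04, 0.01, 0.045, 0.005), non-CV death
        0.02: scaled splits and a residual of 0.9 * 0.98, checked against
        independent arithmetic."""
        split = EventSplit(0.04, 0.01, 0.045, 0.005).scaled(1 - 0.02)
        row = transition_row(STABLE["chd"], split, 0.02)
        assert row[ACUTE_CHD["chd"]] == pytest.approx(0.04 * 0.98)
        assert row[ACUTE_STROKE["both"]] == pytest.approx(0.045 * 0.98)
        assert row[DEAD_CV] == pytest.approx(0.015 * 0.98)
        assert row[DEAD_NONCV] == pytest.approx(0.02)
        assert row[STABLE["chd"]] == pytest.approx(0.9 * 0.98)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_history_merging_routes_to_both(self):
        split = EventSplit(0.1, 0.0, 0.1, 0.0)
        row = transition_row(STABLE["stroke"], split, 0.0)
        assert row[ACUTE_CHD["both"]] == pytest.approx(0.1)
        assert row[ACUTE_STROKE["stroke"]] == pytest.approx(0.1)

    def test_overallocation_raises(self):
        with pytest.raises(NumericError, match="over-allocated"):
            transition_row(STABLE["chd"], EventSplit(0.5, 0.3, 0.3, 0.2), 0.2)


class TestRunCohort:
    def test_deathless_cohort_accrues_full_time(self, deathless_params):
        """No events, no mortality, no discounting: a pure post-CHD cohort
        accrues exactly horizon LY and horizon x 0.84 QALY per patient."""
        p = deathless_params
        p.settings.discount_rate = 0.0
        _, res = run_cohort(p, p.comparator)
        n = p.profile.cohort_size
        assert res.ly / n == pytest.approx(32.0, abs=1e-9)
        assert res.qaly / n == pytest.approx(32.0 * 0.84, abs=1e-9)
        assert res.n_chd_events == 0 and res.n_cv_deaths == 0

    def test_discounted_annuity_closed_form(self, deathless_params):
        """With occupancy frozen at 1, discounted LY equals the closed-form
        annuity: 1 (first year) + sum over t=1..31 of 1.04^-t."""
        p = deathless_params
        _, res = run_cohort(p, p.comparator)
        annuity = 1.0 + sum(1.04 ** -t for t in range(1, 32))
        assert res.ly / p.profile.cohort_size == pytest.approx(annuity,
                                                               abs=1e-9)

    def test_base_case_directional(self, base_params):
        _, inter = run_cohort(base_params, base_params.intervention)
        _, comp = run_cohort(base_params, base_params.comparator)
        assert inter.qaly > comp.qaly
        assert inter.total_cost > comp.total_cost
        assert inter.ly >= inter.qaly  # utilities are below 1

    def test_occupancy_conservation_all_fixtures(self, base_params,
                                                 tiny_params):
        framingham = set_param(base_params, "settings.risk_model_name",
                               "framingham")
        for p in (base_params, tiny_params, framingham):
            for arm in p.arms:
                trace, _ = run_cohort(p, arm)
                sums = trace.occupancy.sum(axis=1)
                np.testing.assert_allclose(sums, 1.0, atol=1e-10)
                assert (trace.occupancy >= -1e-12).all()

    def test_event_arm_ordering(self, base_params):
        """Positive effectiveness deltas can only prevent events."""
        _, inter = run_cohort(base_params, base_params.intervention)
        _, comp = run_cohort(base_params, base_params.comparator)
        assert inter.n_chd_events <= comp.n_chd_events
        assert inter.n_strokes <= comp.n_strokes
        assert inter.n_cv_deaths <= comp.n_cv_deaths

    def test_cost_components_sum_to_total(self, base_params):
        _, res = run_cohort(base_params, base_params.intervention)
        assert res.drug_cost + res.acute_event_cost + res.followup_cost == \
            pytest.approx(res.total_cost, abs=1e-6)


class TestMonotonicity:
    @pytest.mark.parametrize("path,attr", [
        ("utilities.chronic_chd", "qaly"),
        ("utilities.acute_stroke", "qaly"),
    ])
    def test_higher_utility_weakly_raises_qaly(self, tiny_params, path, attr):
        from polypillce.parameters import get_param
        lo = run_cohort(tiny_params, tiny_params.comparator)[1]
        hi_p = set_param(tiny_params, path,
                         min(get_param(tiny_params, path) * 1.05, 1.0))
        hi = run_cohort(hi_p, hi_p.comparator)[1]
        assert getattr(hi, attr) >= getattr(lo, attr)

    @pytest.mark.parametrize("path", [
        "costs.acute_stroke_nonfatal", "costs.annual_post_chd",
    ])
    def test_higher_cost_weakly_raises_total(self, tiny_params, path):
        from polypillce.parameters import get_param
        lo = run_cohort(tiny_params, tiny_params.comparator)[1]
        hi_p = set_param(tiny_params, path, get_param(tiny_params, path) * 1.2)
        hi = run_cohort(hi_p, hi_p.comparator)[1]
        assert hi.total_cost >= lo.total_cost

    def test_higher_discount_rate_lowers_discounted_totals(self, base_params):
        lo = run_cohort(base_params, base_params.comparator)[1]
        hi_p = set_param(base_params, "settings.discount_rate", 0.08)
        hi = run_cohort(hi_p, hi_p.comparator)[1]
        assert hi.ly < lo.ly and hi.qaly < lo.qaly
        assert hi.total_cost < lo.total_cost


def _synthetic_trace(occupancy, lengths):
    cycles = []
    t = 0.0
    for i, ln in enumerate(lengths):
        cycles.append(Cycle(i, t, ln))
        t += ln
    n = len(lengths)
    return CohortTrace(
        schedule=cycles,
        occupancy=occupancy,
        flows=pd.DataFrame(np.zeros((n, 5)),
                           columns=["inc_nonfatal_chd", "inc_fatal_chd",
                                    "inc_nonfatal_stroke", "inc_fatal_stroke",
                                    "inc_noncv_death"]),
        utilities=np.ones(N_STATES),
        followup_costs=np.zeros(N_STATES),
        annual_drug_cost=0.0,
        acute_cost_vector=np.zeros(4),
        discount_rate=0.0,
    )


class TestHalfCycleCorrection:
    def test_constant_occupancy_is_identity(self):
        occ = np.zeros((5, N_STATES))
        occ[:, STABLE["chd"]] = 1.0
        trace = apply_half_cycle_correction(
            _synthetic_trace(occ, [1.0] * 4))
        assert trace.accruals["ly"].sum() == pytest.approx(4.0, abs=1e-12)

    def test_one_cycle_extinction_accrues_half(self):
        occ = np.zeros((2, N_STATES))
        occ[0, STABLE["chd"]] = 1.0
        occ[1, DEAD_NONCV] = 1.0
        trace = apply_half_cycle_correction(_synthetic_trace(occ, [1.0]))
        assert trace.accruals["ly"].sum() == pytest.approx(0.5, abs=1e-12)

    def test_trapezoid_exact_on_linear_decay(self):
        """Occupancy falling linearly 1 -> 0 over four quarters: trapezoid
        accrual equals the analytic integral of the linear survival curve."""
        occ = np.zeros((5, N_STATES))
        for i, frac in enumerate([1.0, 0.75, 0.5, 0.25, 0.0]):
            occ[i, STABLE["chd"]] = frac
            occ[i, DEAD_NONCV] = 1.0 - frac
        trace = apply_half_cycle_correction(
            _synthetic_trace(occ, [0.25] * 4))
        analytic = 0.5  # integral of (1 - t) over [0, 1]
        assert trace.accruals["ly"].sum() == pytest.approx(analytic,
                                                           abs=1e-12)

    def test_trace_export_has_state_and_accrual_columns(self, tiny_params):
        trace, _ = run_cohort(tiny_params, tiny_params.intervention)
        frame = trace.to_frame()
        assert "stable_chd" in frame.columns
        assert "disc_qaly" in frame.columns
        assert len(frame) == 5  # 2-year horizon: 4 quarters + 1 annual
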