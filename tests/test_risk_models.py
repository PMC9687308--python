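"""Risk equations, probability conversions and event splitting."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polypillce.exceptions import ConfigurationError
from polypillce.risk_models import (CoefficientTerm, LifeTable,
                                    RiskModelSpec, framingham_cycle_probs,
                                    horizon_risk, linear_predictor,
                                    noncv_death_prob, risk_to_cycle_prob,
                                    smart_linear_predictor, split_composite)
from polypillce.synthetic_data import generate_life_table


def _spec(terms, s0=0.8107, horizon=10.0, name="smart"):
    return RiskModelSpec(name=name, coefficients=terms, baseline_survival=s0,
                         horizon_years=horizon)


class TestLinearPredictor:
    def test_empty_sum_is_zero(self, base_params):
        assert linear_predictor(base_params.profile, _spec([])) == 0.0

    def test_single_term(self, base_params):
        spec = _spec([CoefficientTerm("sbp", "identity", 1.0)])
        assert linear_predictor(base_params.profile, spec) == 145.1

    def test_unknown_covariate_raises(self, base_params):
        spec = _spec([CoefficientTerm("nonexistent", "identity", 1.0)])
        with pytest.raises(ConfigurationError, match="nonexistent"):
            linear_predictor(base_params.profile, spec)

    def test_packaged_smart_against_hand_computed_sum(self, base_params):
        """Independent hand computation of the dot product from the
        published inputs, term by term."""
        hand = sum([
            (-0.085) * 69.37,
            0.00105 * 69.37 ** 2,
            0.156 * 0.618,
            0.262 * 0.174,
            0.00429 * 145.1,
            0.223 * 0.278,
            0.140 * 0.579,
            0.406 * 0.421,
            0.558 * 0.021,
            0.283 * 0.032,
            0.0229 * 1.0,
            -0.011016292 * 45.2,
            0.002479959 * 190.8,
            -0.0532 * 74.3,
            0.000306 * 74.3 ** 2,
            0.139 * math.log(2.2),
            2.099,
        ])
        lp = smart_linear_predictor(base_params.profile,
                                    base_params.risk_models["smart"])
        assert lp == pytest.approx(hand, abs=1e-12)
        assert lp == pytest.approx(0.19883103689063408, abs=1e-12)


class TestHorizonRisk:
    def test_zero_lp_forces_one_minus_s0(self):
        assert horizon_risk(0.0, _spec([], s0=0.8107)) == pytest.approx(
            1 - 0.8107)

    def test_unit_baseline_survival_gives_zero(self):
        assert horizon_risk(3.7, _spec([], s0=1.0)) == 0.0

    def test_log_two_squares_survival(self):
        # exp(ln 2) = 2, so risk = 1 - S0^2
        assert horizon_risk(math.log(2), _spec([], s0=0.8107)) == \
            pytest.approx(1 - 0.8107 ** 2, abs=1e-12)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_lp(self, a, b):
        spec = _spec([], s0=0.8107)
        if abs(a - b) < 1e-9:  # below float resolution of the map
            return
        lo, hi = sorted((a, b))
        assert horizon_risk(lo, spec) < horizon_risk(hi, spec)


class TestCycleConversion:
    @pytest.mark.parametrize("risk,horizon,length,expected", [
        (1 - 0.8107, 10, 1.0, 1 - 0.8107 ** 0.1),
        (0.0, 10, 0.25, 0.0),
        (1 - 0.8107, 10, 0.25, 1 - 0.8107 ** 0.025),
    ])
    def test_constant_rate_conversion(self, risk, horizon, length, expected):
        assert risk_to_cycle_prob(risk, horizon, length) == pytest.approx(
            expected, abs=1e-12)

    def test_degenerate_certain_risk(self):
        assert risk_to_cycle_prob(1.0, 10, 0.25) == 1.0

    @given(st.floats(0, 0.999))
    @settings(derandomize=True, max_examples=100)
    def test_quarterly_composition_reproduces_annual(self, risk):
        """Surviving four quarterly cycles equals surviving one annual
        cycle, to 1e-12."""
        p_q = risk_to_cycle_prob(risk, 10, 0.25)
        p_a = risk_to_cycle_prob(risk, 10, 1.0)
        assert (1 - p_q) ** 4 == pytest.approx(1 - p_a, abs=1e-12)


class TestSplitComposite:
    def test_hand_computed_split(self, base_params):
        epi = dataclasses.replace(base_params.epi, chd_share_of_events=0.5,
                                  case_fatality_chd=0.2,
                                  case_fatality_stroke=0.1)
        s = split_composite(0.1, epi)
        assert (s.p_nonfatal_chd, s.p_fatal_chd, s.p_nonfatal_stroke,
                s.p_fatal_stroke) == pytest.approx((0.04, 0.01, 0.045, 0.005))

    def test_zero_event_probability(self, base_params):
        s = split_composite(0.0, base_params.epi)
        assert s.total == 0.0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_components_nonnegative_and_resum(self, base_params, p, share,
                                              cf1, cf2):
        epi = dataclasses.replace(base_params.epi, chd_share_of_events=share,
                                  case_fatality_chd=cf1,
                                  case_fatality_stroke=cf2)
        s = split_composite(p, epi)
        parts = (s.p_nonfatal_chd, s.p_fatal_chd, s.p_nonfatal_stroke,
                 s.p_fatal_stroke)
        assert all(x >= 0 for x in parts)
        assert all(x <= p + 1e-12 for x in parts)
        assert sum(parts) == pytest.approx(p, abs=1e-12)


class TestLifeTableMortality:
    def test_beyond_max_age_is_certain_death(self):
        table = generate_life_table()
        assert noncv_death_prob(table.max_age + 40, 0.5, table, 1.0) == 1.0

    def test_quarterly_conversion(self):
        import pandas as pd
        df = pd.DataFrame({"age": [0, 1], "qx_male": [0.04, 1.0],
                           "qx_female": [0.04, 1.0]})
        table = LifeTable(df)
        assert noncv_death_prob(0, 0.5, table, 0.25) == pytest.approx(
            1 - 0.96 ** 0.25, abs=1e-12)

    def test_sex_blend_is_linear(self):
        table = generate_life_table()
        age = 70
        qm = noncv_death_prob(age, 1.0, table, 1.0)
        qf = noncv_death_prob(age, 0.0, table, 1.0)
        qx = table.annual_qx(age, 0.618)
        assert qx == pytest.approx(0.618 * table.annual_qx(age, 1.0)
                                   + 0.382 * table.annual_qx(age, 0.0))
        assert qm > qf  # male excess mortality in the generator


class TestFraminghamRoute:
    def test_unit_rr_reduces_to_primary_equation(self, base_params):
        epi = dataclasses.replace(base_params.epi, rr_recurrent_stroke=1.0)
        chd = _spec([], s0=1.0, name="framingham_chd")  # no CHD hazard
        stroke = base_params.risk_models["framingham_stroke"]
        s = framingham_cycle_probs(base_params.profile, chd, stroke, epi, 1.0)
        primary = risk_to_cycle_prob(
            horizon_risk(linear_predictor(base_params.profile, stroke),
                         stroke), stroke.horizon_years, 1.0)
        assert s.p_nonfatal_chd == 0.0 and s.p_fatal_chd == 0.0
        assert (s.p_nonfatal_stroke + s.p_fatal_stroke) == pytest.approx(
            primary, abs=1e-12)

    def test_zero_hazard_gives_zero_probabilities(self, base_params):
        chd = _spec([], s0=1.0)
        stroke = _spec([], s0=1.0)
        s = framingham_cycle_probs(base_params.profile, chd, stroke,
                                   base_params.epi, 1.0)
        assert s.total == 0.0

    def test_recurrent_stroke_risk_capped_at_one(self, base_params):
        epi = dataclasses.replace(base_params.epi, rr_recurrent_stroke=2.0)
        chd = _spec([], s0=1.0)
        stroke = _spec([], s0=0.4)  # primary 10-y risk 0.6, rr 2 -> capped 1
        s = framingham_cycle_probs(base_params.profile, chd, stroke, epi, 1.0)
        assert (s.p_nonfatal_stroke + s.p_fatal_stroke) == pytest.approx(1.0)

    def test_event_split_stays_stochastic_at_extreme_risk(self, base_params):
        """Even with both equations near saturation the combined split
        must not exceed unit probability (competing-risk combination)."""
        chd = _spec([], s0=0.05)
        stroke = _spec([], s0=0.05)
        s = framingham_cycle_probs(base_params.profile, chd, stroke,
                                   base_params.epi, 1.0)
        assert 0.0 < s.total <= 1.0
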