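"""Gating kinetics, currents, calcium constants and the ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motobist import (
    ModelParameters,
    ParameterError,
    StateVector,
    compute_currents,
    effective_tau,
    nernst_EK,
    rhs,
    steady_state,
    time_constant,
)
from motobist.model import (
    DYNAMIC_GATES,
    GATE_NAMES,
    alpha_from_first_principles,
    equilibrium_calcium,
    pack_params,
    steady_gates,
)


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_EK(140.0, 140.0) == 0.0

    def test_physiological_value(self):
        # 26.54 * ln(4/140): the K+ reversal at normal [K+]_o
        assert nernst_EK(4.0, 140.0) == pytest.approx(26.54 * math.log(4.0 / 140.0))
        assert nernst_EK(4.0, 140.0) == pytest.approx(-94.3589, abs=1e-3)

    def test_monotone_in_K_out(self):
        assert nernst_EK(12.0) > nernst_EK(8.0) > nernst_EK(4.0)

    @pytest.mark.parametrize("kout,kin", [(0.0, 140.0), (-1.0, 140.0), (4.0, 0.0)])
    def test_nonpositive_concentration_rejected(self, kout, kin):
        with pytest.raises(ValueError):
            nernst_EK(kout, kin)


class TestGating:
    @pytest.mark.parametrize("gate,V_half", [
        ("m_NaP", -53.0), ("h_NaF", -55.0), ("m_NaF", -35.0),
        ("m_Kdr", -28.0), ("m_Kv12", -46.0), ("h_Kv12", -54.0),
        ("m_CaL", -27.5), ("h_CaL", -52.4),
    ])
    def test_half_activation(self, gate, V_half):
        assert steady_state(gate, V_half) == pytest.approx(0.5)

    def test_boltzmann_limits(self):
        assert steady_state("m_NaF", 200.0) == pytest.approx(1.0, abs=1e-9)
        assert steady_state("m_NaF", -300.0) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_gate_rejected(self):
        with pytest.raises(KeyError):
            steady_state("m_bogus", -50.0)

    @pytest.mark.parametrize("gate", GATE_NAMES)
    def test_bounded_and_monotone(self, gate):
        # range chosen so the steepest Boltzmann (slope 3 mV) stays
        # representable away from 0/1 in double precision
        V = np.linspace(-100.0, 30.0, 400)
        x = steady_state(gate, V)
        assert np.all((x > 0) & (x < 1))
        d = np.diff(x)
        # activation gates increase with V, inactivation gates decrease
        assert np.all(d > 0) or np.all(d < 0)

    @pytest.mark.parametrize("gate,V,expected", [
        ("h_NaF", -50.0, 15.0),   # both exponentials equal 1 at V = -50
        ("m_Kdr", -40.0, 3.5),    # both exponentials equal 1 at V = -40
        ("m_CaL", 0.0, 0.5),
        ("h_CaL", -70.0, 18.0),
    ])
    def test_time_constants(self, gate, V, expected):
        assert time_constant(gate, V) == pytest.approx(expected)

    @pytest.mark.parametrize("gate", ["m_NaF", "m_NaP"])
    def test_instantaneous_gate_has_no_tau(self, gate):
        with pytest.raises(ValueError):
            time_constant(gate, -50.0)

    @given(st.floats(min_value=-120.0, max_value=40.0))
    @settings(derandomize=True, max_examples=50)
    def test_dynamic_taus_positive(self, V):
        for gate in DYNAMIC_GATES:
            assert time_constant(gate, V) > 0


class TestCalciumConstants:
    def test_effective_tau_default(self):
        assert effective_tau(0.096, 10.0) == pytest.approx(250.0)

    def test_no_cicr_reduces_to_pump(self):
        assert effective_tau(0.0, 10.0) == pytest.approx(10.0)

    def test_intermediate_gain(self):
        assert effective_tau(0.05, 10.0) == pytest.approx(20.0)

    def test_runaway_regime_rejected(self):
        with pytest.raises(ParameterError):
            effective_tau(0.1, 10.0)
        with pytest.raises(ParameterError):
            ModelParameters(k_CICR=0.2)

    def test_alpha_matches_unit_conversion(self):
        # (2 F delta)^-1 in mM cm^2 ms^-1 uA^-1 vs the stored default
        assert alpha_from_first_principles() == pytest.approx(5e-4, rel=0.05)


class TestParameters:
    def test_negative_conductance_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters(g_CAN=-0.1)

    def test_unknown_override_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters().with_(g_bogus=1.0)

    def test_literature_spelling_of_kv12(self):
        p = ModelParameters.from_dict({"g_Kv1.2": 2.0})
        assert p.g_Kv12 == 2.0

    def test_out_of_range_sweep_values_warn_not_raise(self):
        with pytest.warns(UserWarning):
            ModelParameters(K_out=14.0)
        with pytest.warns(UserWarning):
            ModelParameters(g_Kv12=12.0)

    def test_roundtrip(self):
        p = ModelParameters(g_CAN=0.5, K_out=8.0)
        assert ModelParameters.from_dict(p.to_dict()) == p


def _state(V, Ca, params):
    return StateVector(V=V, Ca=Ca, **steady_gates(V))


class TestCurrents:
    def test_each_current_vanishes_at_its_reversal(self):
        p = ModelParameters(g_NaP=0.2, g_Kv12=1.0, g_CAN=0.5, g_KCa=0.5)
        E_K = p.E_K
        cur = compute_currents(_state(p.E_Na, 1e-4, p), p)
        assert cur.I_NaF == pytest.approx(0.0, abs=1e-12)
        assert cur.I_NaP == pytest.approx(0.0, abs=1e-12)
        cur = compute_currents(_state(E_K, 1e-4, p), p)
        assert cur.I_Kdr == pytest.approx(0.0, abs=1e-12)
        assert cur.I_Kv12 == pytest.approx(0.0, abs=1e-12)
        assert cur.I_KCa == pytest.approx(0.0, abs=1e-12)
        cur = compute_currents(_state(p.E_Ca, 1e-4, p), p)
        assert cur.I_CaL == pytest.approx(0.0, abs=1e-12)
        cur = compute_currents(_state(p.E_CAN, 1e-4, p), p)
        assert cur.I_CAN == pytest.approx(0.0, abs=1e-12)
        cur = compute_currents(_state(p.E_L, 1e-4, p), p)
        assert cur.I_L == pytest.approx(0.0, abs=1e-12)

    def test_calcium_gated_currents_half_activate_at_their_K(self):
        p = ModelParameters(g_CAN=0.8, g_KCa=0.6)
        V = -40.0
        cur = compute_currents(_state(V, p.K_CAN, p), p)
        assert cur.I_CAN == pytest.approx(0.5 * p.g_CAN * (V - p.E_CAN))
        cur = compute_currents(_state(V, p.K_d, p), p)
        assert cur.I_KCa == pytest.approx(0.5 * p.g_KCa * (V - p.E_K))


class TestRhs:
    def test_calcium_decay_with_no_influx(self):
        p = ModelParameters(g_CaL=0.0)
        y = _state(-80.0, 1e-3, p).to_array()
        dCa = rhs(0.0, y, 0.0, p)[7]
        assert dCa == pytest.approx(-1e-3 / 250.0)

    def test_passive_rest_at_leak_reversal(self, passive_params):
        y = _state(-80.0, 0.0, passive_params).to_array()
        dy = rhs(0.0, y, 0.0, passive_params)
        assert abs(dy[0]) < 1e-12  # I_L = 0 at E_L
        assert abs(dy[7]) < 1e-15

    def test_equilibrium_calcium_is_a_fixed_point(self, fig2_params):
        V = -55.0
        p = fig2_params
        st_ = StateVector(V=V, Ca=equilibrium_calcium(V, p), **steady_gates(V))
        assert rhs(0.0, st_.to_array(), 0.0, p)[7] == pytest.approx(0.0, abs=1e-15)


class TestCompiledEngineConsistency:
    def test_compiled_rhs_matches_reference(self, fig2_params):
        """The numba right-hand side and the readable one agree to rounding."""
        from motobist.engine import _rhs

        p = fig2_params.with_(g_Kv12=0.5)
        packed = pack_params(p)
        seg = (np.array([1e9]), np.array([0.7]), np.array([0.7]))
        rng = np.random.default_rng(0)
        for _ in range(25):
            V = rng.uniform(-100.0, 40.0)
            y = np.concatenate([[V], rng.uniform(0, 1, 6),
                                [rng.uniform(0, 5e-3)]])
            out = np.empty(8)
            _rhs(0.0, y, packed, *seg, out)
            ref = rhs(0.0, y, 0.7, p)
            np.testing.assert_allclose(out, ref, rtol=1e-12, atol=1e-14)
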