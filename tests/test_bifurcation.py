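"""Spike detection, equilibria, limit cycles, hysteresis and sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motobist import (
    ModelParameters,
    NeverFiresError,
    confirm_bistability_by_steps,
    continuation_diagram,
    detect_spikes,
    find_equilibria,
    measure_hysteresis,
    sweep_bistability_2d,
    threshold_along_axis,
    trace_limit_cycle,
)
from motobist.bifurcation import BistabilityMap
from motobist.simulate import _state_at_voltage, resting_state

from conftest import make_voltage_trace, spike_train_trace


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.05)
        tr = make_voltage_trace(t, np.full_like(t, -80.0))
        assert detect_spikes(tr).size == 0

    def test_counts_synthetic_train(self):
        times = np.arange(10.0, 80.0, 10.0)  # 7 spikes
        tr = spike_train_trace(times, 100.0)
        detected = detect_spikes(tr)
        assert detected.size == 7
        np.testing.assert_allclose(detected, times, atol=0.6)

    def test_threshold_above_trace_max(self):
        tr = spike_train_trace([50.0], 100.0, peak=-20.0)
        assert detect_spikes(tr, threshold=-10.0).size == 0

    @given(st.integers(min_value=1, max_value=12))
    @settings(derandomize=True, max_examples=12, deadline=None)
    def test_refractory_merges_nothing_for_well_separated_spikes(self, n):
        times = 20.0 + 25.0 * np.arange(n)
        tr = spike_train_trace(times, times[-1] + 20.0)
        assert detect_spikes(tr).size == n


class TestEquilibria:
    def test_passive_membrane_has_unique_stable_rest(self, passive_params):
        I = 0.5
        eqs = find_equilibria(passive_params, I)
        assert len(eqs) == 1
        eq = eqs[0]
        assert eq.classification == "stable-node"
        expected_V = passive_params.E_L + I / passive_params.g_L
        assert eq.state.V == pytest.approx(expected_V, abs=1e-6)

    def test_bistable_interval_has_node_and_saddle(self, fig2_params):
        eqs = find_equilibria(fig2_params, 1.4)
        kinds = [e.classification for e in eqs]
        assert "stable-node" in kinds
        assert "saddle" in kinds
        for e in eqs:
            assert e.residual < 1e-8
        saddles = [e for e in eqs if e.classification == "saddle"]
        for s in saddles:
            assert int(np.sum(s.eigenvalues.real > 0)) == 1

    def test_rest_branch_gone_above_fold(self, fig2_params):
        eqs = find_equilibria(fig2_params, 2.5)
        assert not any(e.classification == "stable-node" and e.state.V < -30
                       for e in eqs)


class TestLimitCycle:
    def test_spiking_above_onset_threshold(self, fig2_params):
        kick = _state_at_voltage(-40.0, fig2_params)
        lc = trace_limit_cycle(fig2_params, 2.5, kick)
        assert lc.exists
        assert lc.V_max > -10.0 > lc.V_min
        assert lc.frequency > 0

    def test_silent_below_offset_threshold(self, fig2_params):
        kick = _state_at_voltage(-40.0, fig2_params)
        lc = trace_limit_cycle(fig2_params, 0.5, kick, settle=4000.0)
        assert not lc.exists


@pytest.fixture(scope="module")
def fig8_hyst(fig8_params):
    return measure_hysteresis(fig8_params, max_I=2.0)


class TestHysteresis:
    def test_nap_bistability_at_high_potassium(self, fig8_params, fig8_hyst):
        h = fig8_hyst
        assert h.converged
        assert h.I_down <= h.I_up
        assert h.delta_I > 0.05
        # published panel thresholds for this preset
        assert h.I_up == pytest.approx(0.85, abs=0.1)
        assert h.I_down == pytest.approx(0.45, abs=0.1)

    def test_step_protocol_agrees_with_ramp(self, fig8_params, fig8_hyst):
        assert confirm_bistability_by_steps(fig8_params, fig8_hyst)

    def test_never_fires_signalled(self, fig8_params):
        with pytest.raises(NeverFiresError):
            measure_hysteresis(fig8_params, max_I=0.2,
                               max_phase_duration=5000.0)

    def test_step_confirmation_requires_hysteresis(self, fig8_params, fig8_hyst):
        import dataclasses

        degenerate = dataclasses.replace(fig8_hyst, delta_I=0.0)
        with pytest.raises(ValueError):
            confirm_bistability_by_steps(fig8_params, degenerate)


class TestContinuation:
    def test_coexistence_and_rest_below_cycle(self, fig8_params):
        """Inside the hysteresis interval the rest branch coexists with the
        spiking branch, and for sodium-based bistability the resting
        potential lies below the limit cycle's voltage range."""
        df = continuation_diagram(fig8_params, np.array([0.3, 0.65, 1.0]))
        low, mid, high = df.iloc[0], df.iloc[1], df.iloc[2]
        assert low.rest_exists and not low.bwd_spiking
        assert mid.rest_exists and mid.bwd_spiking and not mid.fwd_spiking
        assert not high.rest_exists and high.fwd_spiking
        assert mid.rest_V < mid.bwd_Vmin


class TestSweep:
    def test_map_shapes_and_threshold_extraction(self):
        base = ModelParameters(g_NaP=0.25)
        bmap = sweep_bistability_2d(
            base,
            ("K_out", np.array([10.0, 12.0])),
            ("g_CAN", np.array([0.0])),
            max_I=2.0, threshold_tol=0.05, max_phase_duration=20000.0,
        )
        assert bmap.delta_I.shape == (2, 1)
        assert not bmap.failures
        # potassium-dependent switch: no hysteresis at 10 mM, hysteresis at 12
        assert bmap.delta_I[0, 0] == 0.0
        assert bmap.delta_I[1, 0] > 0.05
        assert threshold_along_axis(bmap, 0) == 12.0
        df = bmap.to_frame()
        assert set(df.columns) >= {"K_out", "g_CAN", "I_up", "I_down",
                                   "delta_I", "converged"}

    def test_threshold_nan_when_no_bistability(self):
        bmap = BistabilityMap(
            "a", "b", np.array([1.0, 2.0]), np.array([0.0]),
            np.zeros((2, 1)), np.full((2, 1), np.nan),
            np.full((2, 1), np.nan), np.ones((2, 1), dtype=bool))
        assert np.isnan(threshold_along_axis(bmap, 0))
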