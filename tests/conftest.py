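import numpy as np
import pytest

from motobist import ModelParameters, StateVector, Trace
from motobist.presets import get_preset


@pytest.fixture(scope="session")
def fig2_params() -> ModelParameters:
    """The calibrated bistable-cell preset (g_CAN = 0.5)."""
    return get_preset("fig2_ramp").parameters()


@pytest.fixture(scope="session")
def fig8_params() -> ModelParameters:
    """Persistent-sodium bistability preset (g_CAN = 0, g_NaP = 0.4, K_out = 12)."""
    return get_preset("fig8_ramp").parameters()


@pytest.fixture(scope="session")
def passive_params() -> ModelParameters:
    """Leak-only membrane: every active conductance switched off."""
    return ModelParameters(g_NaF=0.0, g_Kdr=0.0, g_CaL=0.0)


def make_voltage_trace(t: np.ndarray, V: np.ndarray) -> Trace:
    """Wrap a bare voltage waveform as a Trace (other states zeroed)."""
    y = np.zeros((t.size, 8))
    y[:, 0] = V
    return Trace(np.asarray(t, float), y, np.zeros_like(t, dtype=float),
                 StateVector.from_array(y[-1]), {"synthetic": True})


def spike_train_trace(spike_times, t_end: float, dt: float = 0.05,
                      baseline: float = -80.0, peak: float = 30.0,
                      half_width: float = 0.5) -> Trace:
    """Synthetic train of triangular spikes on a flat baseline."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    V = np.full_like(t, baseline)
    for ts in spike_times:
        tri = peak - baseline
        m = np.abs(t - ts) <= half_width
        V[m] = baseline + tri * (1 - np.abs(t[m] - ts) / half_width)
    return make_voltage_trace(t, V)
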