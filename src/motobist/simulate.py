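"""Time integration of the motoneuron model under injected-current programs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .engine import integrate_dp54
from .model import (
    DYNAMIC_GATES,
    ModelParameters,
    StateVector,
    equilibrium_calcium,
    pack_params,
    rhs,
    steady_gates,
    steady_state,
)
from .protocols import CurrentProgram, make_constant

__all__ = [
    "Trace",
    "IntegrationError",
    "NoRestingStateError",
    "integrate",
    "resting_state",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "DEFAULT_SAMPLE_DT",
]

# Tight tolerances and 0.05 ms sampling (20 samples/ms) resolve the 1-2 ms
# action-potential upstroke well enough for peak-accurate spike detection.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_SAMPLE_DT = 0.05
DEFAULT_MAX_STEP = 10.0

_TRACE_COLUMNS = ("time_ms", "V_mV", "hNaF", "mKdr", "mKv12", "hKv12",
                  "mCaL", "hCaL", "Ca_mM", "Iinj_uAcm2")


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator fails (step underflow, NaN state)."""


class NoRestingStateError(RuntimeError):
    """Raised when no stable subthreshold equilibrium exists at the given I_inj."""


@dataclass
class Trace:
    """Sampled trajectory of the full state plus the injected current.

    ``t`` is the strictly increasing sample grid in ms, ``y`` the (n, 8)
    state matrix in :data:`motobist.model.STATE_NAMES` order, ``i_inj`` the
    injected current at the sample times.  ``meta`` records solver settings
    and step statistics; integration is deterministic, there is no seed.
    """

    t: np.ndarray
    y: np.ndarray
    i_inj: np.ndarray
    final_state: StateVector
    meta: dict = field(default_factory=dict)

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def Ca(self) -> np.ndarray:
        return self.y[:, 7]

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 <= t <= t1 (final_state is the last sample)."""
        m = (self.t >= t0) & (self.t <= t1)
        return Trace(self.t[m], self.y[m], self.i_inj[m],
                     StateVector.from_array(self.y[m][-1]), dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.t}
        for i, col in enumerate(_TRACE_COLUMNS[1:9]):
            data[col] = self.y[:, i]
        data["Iinj_uAcm2"] = self.i_inj
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        # repr-precision floats make the round-trip lossless
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(_TRACE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing column(s): {sorted(missing)}")
        t = df["time_ms"].to_numpy()
        y = df[list(_TRACE_COLUMNS[1:9])].to_numpy()
        i_inj = df["Iinj_uAcm2"].to_numpy()
        return cls(t, y, i_inj, StateVector.from_array(y[-1]), {"source": str(path)})


def integrate(
    params: ModelParameters,
    program: CurrentProgram,
    init: StateVector,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    sample_dt: float = DEFAULT_SAMPLE_DT,
    max_step: float = DEFAULT_MAX_STEP,
    t_end: float | None = None,
) -> Trace:
    """Integrate the model under ``program`` with adaptive Dormand-Prince 5(4).

    Deterministic: identical inputs and tolerances give bitwise-identical
    samples.  Raises :class:`IntegrationError` on step-size underflow or a
    non-finite state.
    """
    if t_end is None:
        t_end = program.total_duration
    seg_ends, seg_v0, seg_v1 = program.to_arrays()
    y0 = init.to_array()
    ts, ys, y_final, n_acc, n_rej, status = integrate_dp54(
        y0, float(t_end), pack_params(params), seg_ends, seg_v0, seg_v1,
        float(rtol), float(atol), float(sample_dt), float(max_step),
    )
    if status == 1:
        raise IntegrationError(f"step-size underflow at t ~ {ts[-1]:.3f} ms")
    if status == 2:
        raise IntegrationError("non-finite state encountered during integration")
    meta = {
        "rtol": rtol,
        "atol": atol,
        "sample_dt": sample_dt,
        "max_step": max_step,
        "n_accepted": int(n_acc),
        "n_rejected": int(n_rej),
        "method": "dormand-prince-5(4)",
    }
    return Trace(ts, ys, program.value(ts), StateVector.from_array(y_final), meta)


def _state_at_voltage(V: float, params: ModelParameters) -> StateVector:
    """Full state with every gate at steady state and Ca at its fixed point."""
    g = steady_gates(V)
    return StateVector(V=V, Ca=equilibrium_calcium(V, params), **g)


def _net_dVdt(V: float, I_inj: float, params: ModelParameters) -> float:
    """dV/dt at the gate/Ca-consistent state for voltage V (scalar reduction)."""
    st = _state_at_voltage(V, params)
    return float(rhs(0.0, st.to_array(), I_inj, params)[0])


def resting_state(
    params: ModelParameters,
    I_inj: float = 0.0,
    V_guess: float = -80.0,
    V_window: float = 40.0,
    spike_threshold: float = -10.0,
    relax_ms: float = 500.0,
    residual_tol: float = 1e-8,
) -> StateVector:
    """Stable subthreshold equilibrium at constant ``I_inj``.

    The equilibrium problem reduces to a scalar root search in V (all gates at
    steady state, Ca at its V-consistent fixed point); candidate roots near
    ``V_guess`` are polished by a short relaxation integration and accepted
    only if the full right-hand-side residual is below ``residual_tol`` and
    the relaxed state stays put (no spiking).  Raises
    :class:`NoRestingStateError` when no such state exists, e.g. above the
    onset threshold I_up.
    """
    lo, hi = V_guess - V_window, min(V_guess + V_window, spike_threshold)
    grid = np.linspace(lo, hi, 161)
    f = np.array([_net_dVdt(v, I_inj, params) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(grid[i])
        elif f[i] * f[i + 1] < 0:
            roots.append(brentq(_net_dVdt, grid[i], grid[i + 1],
                                args=(I_inj, params), xtol=1e-12))
    # most hyperpolarized candidates first: the resting branch is the low one
    for V0 in sorted(roots):
        cand = _state_at_voltage(float(V0), params)
        tr = integrate(params, make_constant(I_inj, relax_ms), cand,
                       sample_dt=1.0)
        st = tr.final_state
        if st.V > spike_threshold or np.max(tr.V) > spike_threshold:
            continue  # relaxed into spiking: not a rest state
        res = float(np.max(np.abs(rhs(0.0, st.to_array(), I_inj, params))))
        if res < residual_tol and abs(st.V - V0) < 2.0:
            return st
    raise NoRestingStateError(
        f"no stable resting state found at I_inj={I_inj} "
        f"in V range [{lo}, {hi}] mV"
    )
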