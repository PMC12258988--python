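"""Hysteresis detection, equilibrium analysis and bistability maps.

Bistability is operationally defined by ramp hysteresis: during a slow
triangular current ramp the onset threshold I_up (first spike of the
ascending phase) exceeds the offset threshold I_down (last spike of the
descending phase) whenever a silent state and a spiking limit cycle coexist.
The ramp duration is doubled until both thresholds stabilise, so the reported
interval reflects the underlying bifurcation structure rather than ramp-rate
transients.  A step protocol provides an independent confirmation: at an
intermediate current inside (I_down, I_up) the neuron is silent or spiking
depending on its activation history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import ModelParameters, StateVector, rhs
from .protocols import make_constant, make_ramp, make_step_validation
from .simulate import (
    NoRestingStateError,
    Trace,
    integrate,
    resting_state,
    _net_dVdt,
    _state_at_voltage,
)

__all__ = [
    "HysteresisResult",
    "EquilibriumPoint",
    "LimitCycleSummary",
    "BistabilityMap",
    "NeverFiresError",
    "SPIKE_THRESHOLD",
    "SPIKE_REFRACTORY",
    "detect_spikes",
    "measure_hysteresis",
    "confirm_bistability_by_steps",
    "find_equilibria",
    "trace_limit_cycle",
    "continuation_diagram",
    "sweep_bistability_2d",
    "threshold_along_axis",
]

# Action potentials in this model overshoot 0 mV while plateaus stay below
# -20 mV, so an upward crossing of -10 mV with a 2 ms refractory period
# separates spikes from everything else.
SPIKE_THRESHOLD = -10.0
SPIKE_REFRACTORY = 2.0


class NeverFiresError(RuntimeError):
    """Raised when a ramp to max_I elicits no spikes at all."""


def detect_spikes(
    trace: Trace,
    threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
) -> np.ndarray:
    """Spike times (ms): upward threshold crossings at least ``refractory`` apart."""
    V = trace.V
    t = trace.t
    above = V >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if idx.size == 0:
        return np.empty(0)
    times = t[idx]
    kept = [times[0]]
    for ti in times[1:]:
        if ti - kept[-1] >= refractory:
            kept.append(ti)
    return np.asarray(kept)


def _peak_time_after(trace: Trace, t_cross: float, horizon: float = 3.0) -> float:
    """Time of the voltage maximum within ``horizon`` ms after a crossing."""
    m = (trace.t >= t_cross) & (trace.t <= t_cross + horizon)
    if not np.any(m):
        return t_cross
    seg = np.flatnonzero(m)
    return float(trace.t[seg[np.argmax(trace.V[seg])]])


@dataclass
class HysteresisResult:
    """Ramp onset/offset thresholds and the hysteresis width delta_I = I_up - I_down."""

    I_up: float
    I_down: float
    delta_I: float
    ramp_duration: float  # per-phase duration of the converged ramp, ms
    converged: bool
    max_I: float
    down_at_zero: bool = False  # spiking persisted to I = 0 on the descent
    history: list = field(default_factory=list)

    @property
    def is_bistable(self) -> bool:
        return self.delta_I > 0.05


def _ramp_thresholds(params, max_I, phase_duration, threshold, refractory,
                     init, **int_opts):
    program = make_ramp(max_I, phase_duration)
    tr = integrate(params, program, init, **int_opts)
    spikes = detect_spikes(tr, threshold, refractory)
    if spikes.size == 0:
        raise NeverFiresError(
            f"no spikes during ramp to {max_I} uA/cm^2 "
            f"(phase {phase_duration} ms)")
    t_first = _peak_time_after(tr, float(spikes[0]))
    t_last = _peak_time_after(tr, float(spikes[-1]))
    I_up = float(program.value(t_first))
    I_down = float(program.value(t_last))
    down_at_zero = t_last >= 2 * phase_duration - 10 * refractory
    ascending = t_first <= phase_duration
    return I_up, I_down, down_at_zero, ascending


def measure_hysteresis(
    params: ModelParameters,
    max_I: float = 3.0,
    initial_phase_duration: float = 5000.0,
    threshold_tol: float = 0.02,
    max_phase_duration: float = 160000.0,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    **int_opts,
) -> HysteresisResult:
    """Converged ramp hysteresis thresholds.

    Runs the triangular ramp 0 -> max_I -> 0 starting from the resting state
    at I = 0, reading I_up at the first ascending-phase spike peak and I_down
    at the last descending-phase spike peak, then doubles the phase duration
    until both thresholds move by less than ``threshold_tol`` (0.02 uA/cm^2
    by default) or ``max_phase_duration`` is reached.

    Raises :class:`NeverFiresError` if the model never spikes up to ``max_I``.
    If spiking persists all the way down to I = 0, I_down is reported as 0
    with ``down_at_zero`` set.
    """
    init = resting_state(params, 0.0)
    duration = initial_phase_duration
    prev = None
    history = []
    converged = False
    while True:
        I_up, I_down, down_at_zero, ascending = _ramp_thresholds(
            params, max_I, duration, spike_threshold, refractory, init,
            **int_opts)
        if down_at_zero:
            I_down = 0.0
        history.append((duration, I_up, I_down))
        if prev is not None:
            if abs(I_up - prev[0]) < threshold_tol and \
               abs(I_down - prev[1]) < threshold_tol:
                converged = True
                break
        prev = (I_up, I_down)
        if duration * 2 > max_phase_duration:
            break
        duration *= 2
    return HysteresisResult(
        I_up=I_up, I_down=I_down, delta_I=I_up - I_down,
        ramp_duration=duration, converged=converged, max_I=max_I,
        down_at_zero=down_at_zero, history=history,
    )


def confirm_bistability_by_steps(
    params: ModelParameters,
    hyst: HysteresisResult,
    dwell: float = 2000.0,
    settle_frac: float = 0.25,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    **int_opts,
) -> bool:
    """History-dependence check at the midpoint of the hysteresis interval.

    Runs the five-plateau program 0, I_mid, I_high, I_mid, 0 with
    I_mid = (I_up + I_down)/2 and I_high above I_up; returns True iff the
    neuron is silent on the first I_mid plateau and spiking on the second
    (post-activation) one, i.e. the ramp hysteresis reflects true coexistence
    of states rather than a slow transient.
    """
    if hyst.delta_I <= 0:
        raise ValueError("step confirmation requires delta_I > 0")
    I_mid = 0.5 * (hyst.I_up + hyst.I_down)
    I_high = max(hyst.max_I, hyst.I_up + 0.5)
    program = make_step_validation(I_mid, I_high, dwell)
    init = resting_state(params, 0.0)
    tr = integrate(params, program, init, **int_opts)
    spikes = detect_spikes(tr, spike_threshold, refractory)

    def spiking_in(plateau: int) -> bool:
        # judge on the tail of the plateau, past the settling transient
        t0 = plateau * dwell + settle_frac * dwell
        t1 = (plateau + 1) * dwell
        return bool(np.any((spikes >= t0) & (spikes <= t1)))

    return (not spiking_in(1)) and spiking_in(3)


@dataclass
class EquilibriumPoint:
    """A fixed point of the full system with its linear stability class."""

    state: StateVector
    I_inj: float
    classification: str  # "stable-node" | "saddle" | "unstable"
    eigenvalues: np.ndarray
    residual: float


def _jacobian(y: np.ndarray, I_inj: float, params: ModelParameters) -> np.ndarray:
    """Central-difference Jacobian of the full 8-dim right-hand side."""
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        # per-variable scaled steps: mV-sized for V, tiny for gates/Ca
        h = 1e-6 * max(abs(y[j]), 1.0) if j == 0 else 1e-7
        yp = y.copy()
        ym = y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs(0.0, yp, I_inj, params) - rhs(0.0, ym, I_inj, params)) / (2 * h)
    return J


def _classify(eigvals: np.ndarray) -> str:
    n_pos = int(np.sum(eigvals.real > 0))
    if n_pos == 0:
        return "stable-node"
    if n_pos == 1:
        return "saddle"
    return "unstable"


def find_equilibria(
    params: ModelParameters,
    I_inj: float,
    V_range: tuple = (-100.0, 20.0),
    V_step: float = 0.5,
    residual_tol: float = 1e-10,
) -> list:
    """All fixed points in ``V_range``, classified by Jacobian eigenvalues.

    The equilibrium condition reduces to a scalar equation in V (gates at
    steady state, Ca at its fixed point); sign changes of dV/dt on the V grid
    are bracketed and refined by root-finding, each root expanded to the full
    state and residual-checked.
    """
    grid = np.arange(V_range[0], V_range[1] + V_step / 2, V_step)
    fvals = np.array([_net_dVdt(v, I_inj, params) for v in grid])
    points = []
    for i in range(len(grid) - 1):
        if fvals[i] == 0.0:
            V0 = float(grid[i])
        elif fvals[i] * fvals[i + 1] < 0:
            try:
                V0 = float(brentq(_net_dVdt, grid[i], grid[i + 1],
                                  args=(I_inj, params), xtol=1e-13))
            except RuntimeError:  # pragma: no cover - refinement failure
                continue
        else:
            continue
        st = _state_at_voltage(V0, params)
        y = st.to_array()
        res = float(np.max(np.abs(rhs(0.0, y, I_inj, params))))
        if res > residual_tol:
            continue
        eig = np.linalg.eigvals(_jacobian(y, I_inj, params))
        points.append(EquilibriumPoint(
            state=st, I_inj=I_inj, classification=_classify(eig),
            eigenvalues=eig, residual=res,
        ))
    return points


@dataclass
class LimitCycleSummary:
    """Existence and voltage/frequency footprint of the spiking limit cycle."""

    exists: bool
    V_min: float
    V_max: float
    frequency: float  # Hz, mean over the analysis window
    I_inj: float


def trace_limit_cycle(
    params: ModelParameters,
    I_inj: float,
    init: StateVector,
    settle: float = 2000.0,
    window: float = 1000.0,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    **int_opts,
) -> LimitCycleSummary:
    """Integrate ``settle + window`` ms at constant ``I_inj``; summarise the tail."""
    tr = integrate(params, make_constant(I_inj, settle + window), init, **int_opts)
    tail = tr.window(settle, settle + window)
    spikes = detect_spikes(tail, spike_threshold, refractory)
    exists = spikes.size >= 2
    freq = spikes.size / (window / 1000.0) if exists else 0.0
    return LimitCycleSummary(
        exists=bool(exists),
        V_min=float(np.min(tail.V)),
        V_max=float(np.max(tail.V)),
        frequency=float(freq),
        I_inj=I_inj,
    )


def continuation_diagram(
    params: ModelParameters,
    I_grid: np.ndarray,
    settle: float = 2000.0,
    window: float = 1000.0,
    **int_opts,
) -> pd.DataFrame:
    """Quasi-static forward/backward sweep plus per-I equilibrium structure.

    Ascending pass starts from the resting state at the lowest current and
    reuses each final state as the next initial condition; the descending pass
    starts from the spiking state at the highest current.  The coexistence
    interval of the rest branch (a stable subthreshold node) with the
    descending spiking branch equals [I_down, I_up] within grid resolution.

    Returns a long-form table with one row per I value:
    rest_exists, rest_V, n_saddle, forward/backward spiking flags and
    limit-cycle V ranges and frequencies.
    """
    I_grid = np.asarray(I_grid, dtype=float)
    if np.any(np.diff(I_grid) <= 0):
        raise ValueError("I_grid must be sorted ascending")
    rows = {I: {} for I in I_grid}

    for I in I_grid:
        eqs = find_equilibria(params, I)
        stable = [e for e in eqs if e.classification == "stable-node"
                  and e.state.V < SPIKE_THRESHOLD]
        rows[I]["rest_exists"] = bool(stable)
        rows[I]["rest_V"] = min((e.state.V for e in stable), default=np.nan)
        rows[I]["n_saddle"] = sum(e.classification == "saddle" for e in eqs)

    # forward pass from rest
    state = resting_state(params, I_grid[0]) if rows[I_grid[0]]["rest_exists"] \
        else _state_at_voltage(-80.0, params)
    for I in I_grid:
        lc = trace_limit_cycle(params, I, state, settle, window, **int_opts)
        rows[I].update(fwd_spiking=lc.exists, fwd_Vmin=lc.V_min,
                       fwd_Vmax=lc.V_max, fwd_freq=lc.frequency)
        tr = integrate(params, make_constant(I, settle + window), state, **int_opts)
        state = tr.final_state

    # backward pass from the spiking regime at the top of the grid
    state = _state_at_voltage(-40.0, params)  # depolarised kick into spiking
    for I in I_grid[::-1]:
        lc = trace_limit_cycle(params, I, state, settle, window, **int_opts)
        rows[I].update(bwd_spiking=lc.exists, bwd_Vmin=lc.V_min,
                       bwd_Vmax=lc.V_max, bwd_freq=lc.frequency)
        tr = integrate(params, make_constant(I, settle + window), state, **int_opts)
        state = tr.final_state

    df = pd.DataFrame([{"I_inj": I, **rows[I]} for I in I_grid])
    return df


@dataclass
class BistabilityMap:
    """delta_I over a two-parameter grid; 0 (or NaN on failure) = no bistability."""

    axis_a: str
    axis_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    delta_I: np.ndarray  # shape (len(grid_a), len(grid_b))
    I_up: np.ndarray
    I_down: np.ndarray
    converged: np.ndarray
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, a in enumerate(self.grid_a):
            for j, b in enumerate(self.grid_b):
                recs.append({
                    self.axis_a: a, self.axis_b: b,
                    "I_up": self.I_up[i, j], "I_down": self.I_down[i, j],
                    "delta_I": self.delta_I[i, j],
                    "converged": bool(self.converged[i, j]),
                })
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sweep_bistability_2d(
    params: ModelParameters,
    axis_a: tuple,
    axis_b: tuple,
    delta_tol: float = 0.05,
    **hyst_opts,
) -> BistabilityMap:
    """Tile the (axis_a, axis_b) parameter plane with converged ramp hysteresis.

    ``axis_a``/``axis_b`` are (parameter_name, grid) pairs; parameter names
    must be :class:`ModelParameters` fields.  Cells where the model never
    fires contribute delta_I = 0; other per-cell failures are recorded in
    ``failures`` and marked NaN, never fatal.
    """
    name_a, grid_a = axis_a
    name_b, grid_b = axis_b
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    shape = (grid_a.size, grid_b.size)
    dI = np.zeros(shape)
    iu = np.full(shape, np.nan)
    idn = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    failures = []
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            p = params.with_(**{name_a: float(a), name_b: float(b)})
            try:
                h = measure_hysteresis(p, **hyst_opts)
            except NeverFiresError:
                dI[i, j] = 0.0
                conv[i, j] = True
                continue
            except (NoRestingStateError, Exception) as exc:  # noqa: BLE001
                dI[i, j] = np.nan
                failures.append((float(a), float(b), repr(exc)))
                continue
            dI[i, j] = max(h.delta_I, 0.0) if h.delta_I > delta_tol else 0.0
            iu[i, j] = h.I_up
            idn[i, j] = h.I_down
            conv[i, j] = h.converged
    return BistabilityMap(name_a, name_b, grid_a, grid_b, dI, iu, idn,
                          conv, failures)


def threshold_along_axis(bmap: BistabilityMap, j: int,
                         delta_tol: float = 0.05) -> float:
    """Smallest axis-a value with delta_I > tol in column ``j`` (NaN if none)."""
    col = bmap.delta_I[:, j]
    hits = np.flatnonzero(np.nan_to_num(col) > delta_tol)
    return float(bmap.grid_a[hits[0]]) if hits.size else float("nan")
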