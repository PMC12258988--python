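"""Electrophysiological quantification of voltage traces.

Implements the slow afterdepolarization (sADP) / afterhyperpolarization (AHP)
metrics, the three-criterion bistability assessment on holding-current
ladders, and firing-rate dynamics classification (ramping vs adapting), on
simulated traces or imported time/voltage tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bifurcation import SPIKE_REFRACTORY, SPIKE_THRESHOLD, detect_spikes
from .simulate import Trace

__all__ = [
    "SadpMetrics",
    "BistabilityAssessment",
    "RateProfile",
    "InsufficientSpikesError",
    "sadp_metrics",
    "holding_potential",
    "assess_bistability",
    "rate_profile",
    "load_time_voltage_csv",
]


class InsufficientSpikesError(RuntimeError):
    """Raised when fewer than four spikes are available for rate analysis."""


@dataclass
class SadpMetrics:
    """Post-stimulus deflection metrics relative to the holding potential.

    ``amplitude`` is signed: positive for an afterdepolarization (ADP),
    negative for an afterhyperpolarization (AHP).  ``area`` integrates
    (V - holding) over the window; ``duration_at_half_max`` is the time the
    deflection stays beyond half its peak.
    """

    amplitude: float  # mV
    duration_at_half_max: float  # ms
    area: float  # mV*ms
    window: float  # ms
    holding_V: float  # mV
    upstate: bool = False  # spikes present in the window: plateau, not sADP


def holding_potential(trace: Trace, t_ref: float, span: float = 500.0) -> float:
    """Mean V over the ``span`` ms preceding ``t_ref`` (the simulated analog
    of the experimental holding potential)."""
    m = (trace.t >= t_ref - span) & (trace.t < t_ref)
    if not np.any(m):
        raise ValueError("trace does not cover the pre-stimulus span")
    return float(np.mean(trace.V[m]))


def _moving_mean(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def sadp_metrics(
    trace: Trace,
    stim_end: float,
    window: float = 7500.0,
    holding_V: float | None = None,
    stim_start: float | None = None,
    smooth_ms: float = 50.0,
    spike_threshold: float = SPIKE_THRESHOLD,
) -> SadpMetrics:
    """sADP/AHP amplitude, half-max duration and area after ``stim_end``.

    The window runs from the stimulus end to the onset of the hyperpolarizing
    test pulse (7.5 s by default).  If ``holding_V`` is not given it is taken
    as the mean V over the 500 ms preceding ``stim_start``.  The half-max
    duration is measured on a 50 ms moving-mean smoothed trace to suppress
    channel-kinetics ripple (set ``smooth_ms=0`` for the raw trace).  If
    spikes occur inside the window the neuron is in an upstate and the
    metrics are flagged.
    """
    if trace.t[-1] < stim_end + window - 1e-9:
        raise ValueError(
            f"trace ends at {trace.t[-1]} ms, before stim_end + window = "
            f"{stim_end + window} ms")
    if holding_V is None:
        if stim_start is None:
            raise ValueError("provide holding_V or stim_start")
        holding_V = holding_potential(trace, stim_start)
    win = trace.window(stim_end, stim_end + window)
    upstate = detect_spikes(win, spike_threshold).size > 0

    dev = win.V - holding_V
    area = float(np.trapezoid(dev, win.t))

    dt = float(np.median(np.diff(win.t)))
    nker = max(1, int(round(smooth_ms / dt)))
    dev_s = _moving_mean(dev, nker)
    ipk = int(np.argmax(np.abs(dev_s)))
    amplitude = float(dev_s[ipk])
    if amplitude == 0.0:
        return SadpMetrics(0.0, 0.0, area, window, holding_V, upstate)
    half = amplitude / 2.0
    beyond = dev_s >= half if amplitude > 0 else dev_s <= half
    duration = float(np.sum(beyond) * dt)
    return SadpMetrics(amplitude, duration, area, window, holding_V, upstate)


@dataclass
class BistabilityAssessment:
    """Outcome of the three-criterion bistability test on a holding ladder.

    A holding level counts as bistable when (1) the pre-stimulus potential
    stays hyperpolarized below spike threshold (downstate), (2) firing is
    self-sustained after the pulse (upstate), and (3) a brief hyperpolarizing
    pulse resets the neuron to the downstate.
    """

    is_bistable: bool
    Vh_min: float
    Vh_max: float
    delta_V: float
    I_min: float
    I_max: float
    delta_I_holding: float
    per_level: pd.DataFrame


def assess_bistability(
    traces: list,
    programs: list,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    sustain_span: float = 1000.0,
) -> BistabilityAssessment:
    """Apply the three bistability criteria across a holding-current ladder.

    ``traces``/``programs`` are parallel lists from integrating the programs
    returned by :func:`motobist.protocols.make_holding_ladder` (the programs
    carry the stimulus/hyperpulse landmark times).  Vh_min/Vh_max are the
    extreme pre-pulse potentials among levels passing all three criteria;
    the current ranges come from the corresponding holding currents.
    """
    rows = []
    for tr, prog in zip(traces, programs):
        mk = prog.marks
        hold_I = mk["holding"]
        spikes = detect_spikes(tr, spike_threshold, refractory)
        pre_V = holding_potential(tr, mk["stim_start"])
        pre_spikes = np.any(spikes < mk["stim_start"])
        downstate = (pre_V < spike_threshold) and not pre_spikes
        # self-sustained firing right up to the hyperpolarizing test pulse
        sustained = bool(np.any(
            (spikes >= mk["hyper_start"] - sustain_span)
            & (spikes < mk["hyper_start"])))
        resets = not np.any(spikes > mk["hyper_end"] + 100.0)
        rows.append({
            "holding_I": hold_I, "pre_V": pre_V,
            "downstate": downstate, "upstate_sustained": sustained,
            "hyperpulse_resets": resets,
            "bistable": downstate and sustained and resets,
        })
    df = pd.DataFrame(rows)
    ok = df[df["bistable"]]
    if ok.empty:
        return BistabilityAssessment(False, np.nan, np.nan, 0.0,
                                     np.nan, np.nan, 0.0, df)
    return BistabilityAssessment(
        is_bistable=True,
        Vh_min=float(ok["pre_V"].min()),
        Vh_max=float(ok["pre_V"].max()),
        delta_V=float(ok["pre_V"].max() - ok["pre_V"].min()),
        I_min=float(ok["holding_I"].min()),
        I_max=float(ok["holding_I"].max()),
        delta_I_holding=float(ok["holding_I"].max() - ok["holding_I"].min()),
        per_level=df,
    )


@dataclass
class RateProfile:
    """Instantaneous firing rate series and its linear trend."""

    spike_times: np.ndarray  # ms
    freq_times: np.ndarray  # ms, ISI midpoints
    freq: np.ndarray  # Hz
    slope: float  # Hz/s
    classification: str  # "ramping" | "adapting" | "flat"


def rate_profile(
    trace: Trace,
    window: tuple | None = None,
    spike_threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    dead_band_frac: float = 0.05,
) -> RateProfile:
    """Firing-rate trend within ``window``: ramping, adapting or flat.

    The instantaneous frequency is the reciprocal inter-spike interval placed
    at the ISI midpoint; the least-squares slope of frequency versus time is
    compared against a dead band of +-``dead_band_frac`` of the mean rate per
    second.  Requires at least four spikes.
    """
    spikes = detect_spikes(trace, spike_threshold, refractory)
    if window is not None:
        spikes = spikes[(spikes >= window[0]) & (spikes <= window[1])]
    if spikes.size < 4:
        raise InsufficientSpikesError(
            f"rate analysis needs >= 4 spikes, got {spikes.size}")
    isi = np.diff(spikes)  # ms
    freq = 1000.0 / isi  # Hz
    mids = 0.5 * (spikes[:-1] + spikes[1:])
    slope_ms = np.polyfit(mids, freq, 1)[0]  # Hz/ms
    slope = float(slope_ms * 1000.0)  # Hz/s
    band = dead_band_frac * float(np.mean(freq))  # Hz per s
    if slope > band:
        cls = "ramping"
    elif slope < -band:
        cls = "adapting"
    else:
        cls = "flat"
    return RateProfile(spikes, mids, freq, slope, cls)


def load_time_voltage_csv(path) -> Trace:
    """Read a generic two-column (time_ms, V_mV) CSV as a voltage-only trace."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("expected at least two columns: time_ms, V_mV")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    V = df.iloc[:, 1].to_numpy(dtype=float)
    y = np.zeros((t.size, 8))
    y[:, 0] = V
    from .model import StateVector
    return Trace(t, y, np.zeros_like(t), StateVector.from_array(y[-1]),
                 {"source": str(path), "voltage_only": True})
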