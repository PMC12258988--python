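"""Injected-current programs: ramps, steps, pulses and holding ladders.

A :class:`CurrentProgram` is an ordered list of segments, each either constant
or a linear ramp, evaluable at any time in [0, total_duration].  Jumps are
allowed at segment boundaries; within a segment the waveform is continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment",
    "CurrentProgram",
    "make_constant",
    "make_ramp",
    "make_step_validation",
    "make_pulse",
    "make_holding_ladder",
]


@dataclass(frozen=True)
class Segment:
    duration: float  # ms
    start_value: float  # uA/cm^2
    end_value: float  # uA/cm^2

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment duration must be positive, got {self.duration}")

    @property
    def kind(self) -> str:
        return "constant" if self.start_value == self.end_value else "linear-ramp"


@dataclass(frozen=True)
class CurrentProgram:
    """Piecewise-linear injected current I_inj(t).

    ``marks`` optionally labels protocol landmarks (e.g. pulse onset/offset
    times) for downstream feature extraction.
    """

    segments: tuple
    marks: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("program needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Segment end times, strictly increasing, last equals total_duration."""
        return np.cumsum([s.duration for s in self.segments])

    def value(self, t):
        """I_inj at time(s) ``t``; times beyond the program hold the final value."""
        t = np.asarray(t, dtype=float)
        ends = self.boundaries
        starts = ends - np.array([s.duration for s in self.segments])
        out = np.full(t.shape, self.segments[-1].end_value)
        for s, t0, t1 in zip(self.segments, starts, ends):
            m = (t >= t0) & (t < t1) if t1 < ends[-1] else (t >= t0) & (t <= t1)
            if s.duration > 0:
                frac = (t[m] - t0) / s.duration
                out[m] = s.start_value + frac * (s.end_value - s.start_value)
        return out[()] if out.ndim == 0 else out

    def to_arrays(self):
        """(end_times, start_values, end_values) for the compiled integrator."""
        ends = self.boundaries.astype(float)
        v0 = np.array([s.start_value for s in self.segments], dtype=float)
        v1 = np.array([s.end_value for s in self.segments], dtype=float)
        return ends, v0, v1

    def to_spec(self) -> list:
        return [
            {"duration": s.duration, "kind": s.kind,
             "start_value": s.start_value, "end_value": s.end_value}
            for s in self.segments
        ]

    @classmethod
    def from_spec(cls, spec: list) -> "CurrentProgram":
        segs = []
        for d in spec:
            start = float(d["start_value"])
            end = float(d.get("end_value", start))
            if d.get("kind", "constant") == "constant" and start != end:
                raise ValueError("constant segment with start_value != end_value")
            segs.append(Segment(float(d["duration"]), start, end))
        return cls(tuple(segs))


def make_constant(I: float, duration: float) -> CurrentProgram:
    """Hold ``I`` uA/cm^2 for ``duration`` ms."""
    return CurrentProgram((Segment(duration, I, I),))


def make_ramp(max_I: float, phase_duration: float) -> CurrentProgram:
    """Symmetric triangular ramp 0 -> max_I -> 0, each phase ``phase_duration`` ms.

    This is the bidirectional ramp used to reveal hysteresis: the onset
    threshold I_up is read on the ascending phase and the offset threshold
    I_down on the descending phase.
    """
    if max_I <= 0:
        raise ValueError(f"max_I must be positive, got {max_I}")
    return CurrentProgram(
        (Segment(phase_duration, 0.0, max_I), Segment(phase_duration, max_I, 0.0)),
        marks={"peak_time": phase_duration},
    )


def make_step_validation(I_mid: float, I_high: float, dwell: float) -> CurrentProgram:
    """Five-plateau history-dependence protocol: 0, I_mid, I_high, I_mid, 0.

    At the intermediate level the neuron should be silent before activation
    and spiking after, if and only if the hysteresis interval is real.  The
    degenerate case I_mid == I_high collapses to a three-level program and is
    allowed.
    """
    if I_mid > I_high:
        raise ValueError(f"I_mid={I_mid} must not exceed I_high={I_high}")
    levels = [0.0, I_mid, I_high, I_mid, 0.0]
    segs = tuple(Segment(dwell, v, v) for v in levels)
    marks = {f"plateau{i}_start": i * dwell for i in range(5)}
    marks["dwell"] = dwell
    return CurrentProgram(segs, marks=marks)


def make_pulse(
    amplitude: float,
    pulse_dur: float,
    baseline: float = 0.0,
    pre: float = 1000.0,
    post: float = 8000.0,
) -> CurrentProgram:
    """Rectangular current pulse of ``amplitude`` on top of ``baseline``."""
    segs = (
        Segment(pre, baseline, baseline),
        Segment(pulse_dur, baseline + amplitude, baseline + amplitude),
        Segment(post, baseline, baseline),
    )
    return CurrentProgram(segs, marks={"stim_start": pre, "stim_end": pre + pulse_dur})


def make_holding_ladder(
    pulse_amp: float,
    holding_values,
    pulse_dur: float = 2000.0,
    pre: float = 2000.0,
    hyperpulse_amp: float = -2.0,
    hyperpulse_delay: float = 7500.0,
    hyperpulse_dur: float = 500.0,
    tail: float = 2000.0,
) -> list:
    """One program per holding current, emulating the experimental ladder.

    Each program holds the baseline current, delivers a 2-s depolarizing
    pulse, waits ``hyperpulse_delay`` (7.5 s by default, the post-stimulus
    observation window), then applies a brief hyperpolarizing test pulse that
    should reset a genuine plateau to the downstate.
    """
    if pulse_dur <= 0:
        raise ValueError("pulse_dur must be positive")
    programs = []
    for hold in holding_values:
        segs = (
            Segment(pre, hold, hold),
            Segment(pulse_dur, hold + pulse_amp, hold + pulse_amp),
            Segment(hyperpulse_delay, hold, hold),
            Segment(hyperpulse_dur, hold + hyperpulse_amp, hold + hyperpulse_amp),
            Segment(tail, hold, hold),
        )
        marks = {
            "holding": hold,
            "stim_start": pre,
            "stim_end": pre + pulse_dur,
            "hyper_start": pre + pulse_dur + hyperpulse_delay,
            "hyper_end": pre + pulse_dur + hyperpulse_delay + hyperpulse_dur,
        }
        programs.append(CurrentProgram(segs, marks=marks))
    return programs
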