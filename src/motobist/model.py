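"""Conductance-based single-compartment spinal motoneuron model.

The membrane carries eight transmembrane currents: the spike-generating fast
sodium (I_NaF) and delayed-rectifier potassium (I_Kdr) currents, the
persistent sodium current (I_NaP), a slowly inactivating Kv1.2-type potassium
current (I_Kv1.2), a high-voltage-activated L-type calcium current (I_CaL),
the calcium-activated non-specific cation current (I_CAN, TRPM5-associated),
the calcium-dependent potassium current (I_KCa, SK-associated), and an ohmic
leak (I_L).  Voltage obeys the current-balance equation

    C dV/dt = -I_NaF - I_NaP - I_Kdr - I_Kv1.2 - I_CaL - I_KCa - I_CAN
              - I_L + I_inj ,

and intracellular calcium obeys

    dCa/dt = -f * alpha * I_CaL + k_CICR * Ca - Ca / tau_Ca ,

where the middle term is calcium-induced calcium release (CICR): release from
internal stores at a rate proportional to the cytosolic concentration.  With
CICR the calcium clearance time constant lengthens from tau_Ca to the
effective value tau_eff = (1/tau_Ca - k_CICR)^-1, which is what allows Ca to
accumulate across spikes and recruit I_CAN.

Units are fixed throughout: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2, mM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "CurrentSet",
    "ParameterError",
    "STATE_NAMES",
    "GATE_NAMES",
    "DYNAMIC_GATES",
    "INSTANTANEOUS_GATES",
    "nernst_EK",
    "effective_tau",
    "steady_state",
    "time_constant",
    "compute_currents",
    "rhs",
    "steady_gates",
    "equilibrium_calcium",
    "pack_params",
    "alpha_from_first_principles",
]

# Faraday's constant, C/mol, and the sub-membrane shell thickness (cm) that
# together fix the current-to-concentration conversion alpha = 1/(2 F delta).
FARADAY = 9.648e4
SHELL_THICKNESS_CM = 0.1e-4  # 0.1 um

STATE_NAMES = ("V", "h_NaF", "m_Kdr", "m_Kv12", "h_Kv12", "m_CaL", "h_CaL", "Ca")

#: gates integrated as state variables, in state-vector order
DYNAMIC_GATES = ("h_NaF", "m_Kdr", "m_Kv12", "h_Kv12", "m_CaL", "h_CaL")
#: gates evaluated algebraically from V at every instant
INSTANTANEOUS_GATES = ("m_NaF", "m_NaP")
GATE_NAMES = INSTANTANEOUS_GATES + DYNAMIC_GATES


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


def nernst_EK(K_out: float, K_in: float = 140.0, coeff: float = 26.54) -> float:
    """Potassium reversal potential E_K = coeff * ln([K+]_o / [K+]_i), in mV.

    The coefficient is RT/F near recording temperature, so the logarithm is
    natural.  Strictly increasing in ``K_out``.
    """
    if K_out <= 0 or K_in <= 0:
        raise ValueError(
            f"ionic concentrations must be positive, got K_out={K_out}, K_in={K_in}"
        )
    return coeff * math.log(K_out / K_in)


def effective_tau(k_CICR: float, tau_Ca: float) -> float:
    """Effective calcium clearance time constant (1/tau_Ca - k_CICR)^-1, ms.

    CICR feeds calcium back into the cytosol at rate k_CICR*Ca, partially
    cancelling the pump term -Ca/tau_Ca; the net linear decay rate is
    1/tau_Ca - k_CICR.  k_CICR >= 1/tau_Ca would make calcium grow without
    bound and is rejected.
    """
    if tau_Ca <= 0:
        raise ParameterError(f"tau_Ca must be positive, got {tau_Ca}")
    if k_CICR >= 1.0 / tau_Ca:
        raise ParameterError(
            f"k_CICR={k_CICR} >= 1/tau_Ca={1.0 / tau_Ca}: runaway calcium regime"
        )
    return 1.0 / (1.0 / tau_Ca - k_CICR)


def alpha_from_first_principles(
    faraday: float = FARADAY, delta_cm: float = SHELL_THICKNESS_CM
) -> float:
    """Current-to-concentration factor alpha = (2 F delta)^-1 in mM cm^2 ms^-1 uA^-1.

    A calcium current density of 1 uA/cm^2 = 1e-6 C s^-1 cm^-2 carries
    1e-6/(2F) mol s^-1 cm^-2 of Ca2+ (valence 2) into a shell of volume
    ``delta`` cm^3 per cm^2 of membrane; converting mol/cm^3 to mM (1e6) and
    s to ms (1e-3) leaves 1/(2 F delta) * 1e-6 * 1e6 * 1e-3.
    """
    return 1.0 / (2.0 * faraday * delta_cm) * 1e-3


@dataclass(frozen=True)
class ModelParameters:
    """Every constant of the model equations, with the published defaults.

    Conductances in mS/cm^2; the modulatory ones (g_NaP, g_Kv12, g_CAN,
    g_KCa) default to zero and are raised per experiment.  ``g_Kv12`` is the
    Kv1.2 conductance (written g_Kv1.2 in the literature; the dot is not a
    valid identifier character).
    """

    C: float = 1.0  # uF/cm^2
    g_NaF: float = 120.0
    g_Kdr: float = 100.0
    g_NaP: float = 0.0
    g_Kv12: float = 0.0
    g_CaL: float = 0.05
    g_CAN: float = 0.0
    g_KCa: float = 0.0
    g_L: float = 0.1
    E_Na: float = 55.0  # mV
    E_Ca: float = 80.0  # mV, held constant (not Nernst-updated with Ca)
    E_CAN: float = 0.0  # mV
    E_L: float = -80.0  # mV
    K_out: float = 4.0  # mM
    K_in: float = 140.0  # mM
    nernst_coeff: float = 26.54  # mV
    K_CAN: float = 0.74e-3  # mM, half-activation Ca of I_CAN
    K_d: float = 0.2e-3  # mM, half-activation Ca of I_KCa
    f: float = 0.01  # unbound fraction of entering Ca
    alpha: float = 5e-4  # mM cm^2 ms^-1 uA^-1
    k_CICR: float = 0.096  # ms^-1
    tau_Ca: float = 10.0  # ms
    tau_CaL_m: float = 0.5  # ms
    tau_CaL_h: float = 18.0  # ms

    def __post_init__(self) -> None:
        for name in ("g_NaF", "g_Kdr", "g_NaP", "g_Kv12", "g_CaL", "g_CAN",
                     "g_KCa", "g_L"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("C", "K_out", "K_in", "tau_Ca", "tau_CaL_m", "tau_CaL_h"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.k_CICR >= 1.0 / self.tau_Ca:
            raise ParameterError(
                f"k_CICR={self.k_CICR} >= 1/tau_Ca={1.0 / self.tau_Ca}: "
                "runaway calcium regime"
            )
        # published sweep ranges; probing the edges is legitimate, so warn only
        if not 0.0 <= self.g_Kv12 <= 10.0:
            warnings.warn(f"g_Kv12={self.g_Kv12} outside the published range [0, 10]",
                          stacklevel=2)
        if not 4.0 <= self.K_out <= 12.0:
            warnings.warn(f"K_out={self.K_out} outside the published range [4, 12] mM",
                          stacklevel=2)

    @property
    def E_K(self) -> float:
        """Potassium reversal potential, mV, from the Nernst equation."""
        return nernst_EK(self.K_out, self.K_in, self.nernst_coeff)

    @property
    def tau_eff(self) -> float:
        """Effective calcium clearance time constant, ms."""
        return effective_tau(self.k_CICR, self.tau_Ca)

    def with_(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        # accept the literature spelling for the Kv1.2 conductance
        if "g_Kv1.2" in d:
            d["g_Kv12"] = d.pop("g_Kv1.2")
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ParameterError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class StateVector:
    """The eight dynamical variables: V plus six gates plus calcium."""

    V: float
    h_NaF: float
    m_Kdr: float
    m_Kv12: float
    h_Kv12: float
    m_CaL: float
    h_CaL: float
    Ca: float

    def to_array(self) -> np.ndarray:
        return np.array([self.V, self.h_NaF, self.m_Kdr, self.m_Kv12,
                         self.h_Kv12, self.m_CaL, self.h_CaL, self.Ca])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*(float(v) for v in y))

    def validate(self, tol: float = 1e-9) -> None:
        for name in DYNAMIC_GATES:
            x = getattr(self, name)
            if not -tol <= x <= 1.0 + tol:
                raise ValueError(f"gate {name}={x} outside [0, 1]")
        if self.Ca < -tol:
            raise ValueError(f"Ca={self.Ca} negative")


@dataclass(frozen=True)
class CurrentSet:
    """All eight transmembrane currents at one state, uA/cm^2, outward positive."""

    I_NaF: float
    I_NaP: float
    I_Kdr: float
    I_Kv12: float
    I_CaL: float
    I_CAN: float
    I_KCa: float
    I_L: float

    @property
    def total(self) -> float:
        return (self.I_NaF + self.I_NaP + self.I_Kdr + self.I_Kv12
                + self.I_CaL + self.I_CAN + self.I_KCa + self.I_L)


# ---------------------------------------------------------------------------
# Gating kinetics.  All activation/inactivation curves are Boltzmann functions
# x_inf(V) = 1/(1 + exp(-(V - V_half)/k)) with k < 0 for inactivation gates.
# ---------------------------------------------------------------------------

def _boltz(V, V_half, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - V_half) / k))


_STEADY = {
    "m_NaF": (-35.0, 7.8),
    "h_NaF": (-55.0, -7.0),
    "m_NaP": (-53.0, 3.0),
    "m_Kdr": (-28.0, 15.0),
    "m_Kv12": (-46.0, 6.9),
    "h_Kv12": (-54.0, -7.1),
    "m_CaL": (-27.5, 5.7),
    "h_CaL": (-52.4, -5.2),
}


def steady_state(gate: str, V):
    """Steady-state activation/inactivation of ``gate`` at voltage ``V`` (mV)."""
    try:
        V_half, k = _STEADY[gate]
    except KeyError:
        raise KeyError(f"unknown gate {gate!r}; one of {sorted(_STEADY)}") from None
    return _boltz(V, V_half, k)


def _tau_NaF(V):
    V = np.asarray(V, dtype=float)
    return 30.0 / (np.exp((V + 50.0) / 15.0) + np.exp(-(V + 50.0) / 16.0))


def _tau_Kdr(V):
    V = np.asarray(V, dtype=float)
    return 7.0 / (np.exp((V + 40.0) / 40.0) + np.exp(-(V + 40.0) / 50.0))


def _tau_Kv12_m(V):
    V = np.asarray(V, dtype=float)
    return 2.44 + 18.387 / (np.exp(-(V - 25.645) / 21.633)
                            + np.exp((V + 4.42) / 45.9))


def _tau_Kv12_h(V):
    V = np.asarray(V, dtype=float)
    return 74.74 / (0.00015 * np.exp(-(V + 13.0) / 15.0)
                    + 0.06 / (1.0 + np.exp(-(V + 68.0) / 12.0)))


def time_constant(gate: str, V, params: ModelParameters | None = None):
    """Voltage-dependent time constant of a dynamic gate, ms.

    Instantaneous gates (m_NaF, m_NaP) have no time constant and raise.
    """
    if gate in INSTANTANEOUS_GATES:
        raise ValueError(f"gate {gate!r} is instantaneous and has no time constant")
    p = params or _DEFAULT_PARAMS
    if gate == "h_NaF":
        return _tau_NaF(V)
    if gate == "m_Kdr":
        return _tau_Kdr(V)
    if gate == "m_Kv12":
        return _tau_Kv12_m(V)
    if gate == "h_Kv12":
        return _tau_Kv12_h(V)
    if gate == "m_CaL":
        return np.full_like(np.asarray(V, dtype=float), p.tau_CaL_m)[()]
    if gate == "h_CaL":
        return np.full_like(np.asarray(V, dtype=float), p.tau_CaL_h)[()]
    raise KeyError(f"unknown gate {gate!r}")


def steady_gates(V: float) -> dict:
    """All six dynamic gates at their steady state for voltage ``V``."""
    return {g: float(steady_state(g, V)) for g in DYNAMIC_GATES}


def equilibrium_calcium(V: float, params: ModelParameters) -> float:
    """Calcium fixed point with gates at steady state: Ca* = -f*alpha*I_CaL*tau_eff.

    I_CaL is inward (negative) below E_Ca, so Ca* >= 0 at physiological V.
    """
    m = float(steady_state("m_CaL", V))
    h = float(steady_state("h_CaL", V))
    I_CaL = params.g_CaL * m * h * (V - params.E_Ca)
    return max(0.0, -params.f * params.alpha * I_CaL * params.tau_eff)


def compute_currents(state: StateVector, params: ModelParameters) -> CurrentSet:
    """Evaluate all eight membrane currents at ``state`` (outward positive).

    The instantaneous activations m_NaF and m_NaP are evaluated from V on the
    fly; I_NaF uses the m^3 h convention and I_Kdr the m^4 convention.  The
    calcium-gated currents saturate as Ca/(Ca + K_half).
    """
    p = params
    V, Ca = state.V, state.Ca
    E_K = p.E_K
    m_naf = float(steady_state("m_NaF", V))
    m_nap = float(steady_state("m_NaP", V))
    return CurrentSet(
        I_NaF=p.g_NaF * m_naf**3 * state.h_NaF * (V - p.E_Na),
        I_NaP=p.g_NaP * m_nap * (V - p.E_Na),  # non-inactivating: h_NaP == 1
        I_Kdr=p.g_Kdr * state.m_Kdr**4 * (V - E_K),
        I_Kv12=p.g_Kv12 * state.m_Kv12 * state.h_Kv12 * (V - E_K),
        I_CaL=p.g_CaL * state.m_CaL * state.h_CaL * (V - p.E_Ca),
        I_CAN=p.g_CAN * Ca / (Ca + p.K_CAN) * (V - p.E_CAN),
        I_KCa=p.g_KCa * Ca / (Ca + p.K_d) * (V - E_K),
        I_L=p.g_L * (V - p.E_L),
    )


def rhs(t: float, y: np.ndarray, I_inj: float, params: ModelParameters) -> np.ndarray:
    """Full right-hand side of the model ODE system (reference implementation).

    The time-critical integrator uses a compiled twin of this function
    (:mod:`motobist.engine`); this version is the readable oracle used for
    residual checks, equilibrium refinement and Jacobians.
    """
    state = StateVector.from_array(y)
    p = params
    cur = compute_currents(state, p)
    dV = (-cur.total + I_inj) / p.C
    V = state.V
    dy = np.empty(8)
    dy[0] = dV
    dy[1] = (float(steady_state("h_NaF", V)) - state.h_NaF) / float(_tau_NaF(V))
    dy[2] = (float(steady_state("m_Kdr", V)) - state.m_Kdr) / float(_tau_Kdr(V))
    dy[3] = (float(steady_state("m_Kv12", V)) - state.m_Kv12) / float(_tau_Kv12_m(V))
    dy[4] = (float(steady_state("h_Kv12", V)) - state.h_Kv12) / float(_tau_Kv12_h(V))
    dy[5] = (float(steady_state("m_CaL", V)) - state.m_CaL) / p.tau_CaL_m
    dy[6] = (float(steady_state("h_CaL", V)) - state.h_CaL) / p.tau_CaL_h
    dy[7] = -p.f * p.alpha * cur.I_CaL + p.k_CICR * state.Ca - state.Ca / p.tau_Ca
    return dy


# ---------------------------------------------------------------------------
# Packing for the compiled integrator
# ---------------------------------------------------------------------------

# index layout of the flat parameter vector consumed by motobist.engine
P_C, P_GNAF, P_GKDR, P_GNAP, P_GKV12, P_GCAL, P_GCAN, P_GKCA, P_GL = range(9)
P_ENA, P_ECA, P_ECAN, P_EL, P_EK = range(9, 14)
P_KCAN, P_KD, P_F, P_ALPHA, P_KCICR, P_TAUCA, P_TAUCALM, P_TAUCALH = range(14, 22)
N_PACKED = 22


def pack_params(params: ModelParameters) -> np.ndarray:
    """Flatten a parameter set (with E_K resolved) for the compiled engine."""
    p = params
    return np.array([
        p.C, p.g_NaF, p.g_Kdr, p.g_NaP, p.g_Kv12, p.g_CaL, p.g_CAN, p.g_KCa,
        p.g_L, p.E_Na, p.E_Ca, p.E_CAN, p.E_L, p.E_K, p.K_CAN, p.K_d, p.f,
        p.alpha, p.k_CICR, p.tau_Ca, p.tau_CaL_m, p.tau_CaL_h,
    ])


_DEFAULT_PARAMS = ModelParameters()
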