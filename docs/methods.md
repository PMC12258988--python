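# Methods

## Model

The model is a single-compartment spinal motoneuron with eight transmembrane
currents and one intracellular calcium pool.  State variables are the
membrane potential V, six gating variables (h_NaF, m_Kdr, m_Kv12, h_Kv12,
m_CaL, h_CaL) and the cytosolic calcium concentration Ca — eight ODEs in
total.  Two activations are treated algebraically: m_NaF and m_NaP are
instantaneous functions of V, and the persistent sodium current does not
inactivate (h_NaP ≡ 1), so neither enters the state.  Every steady-state
curve is a Boltzmann function; the voltage-dependent time constants of
h_NaF, m_Kdr and the two Kv1.2 gates are sums of exponentials, and the
L-type calcium gates have fixed time constants (0.5 and 18 ms).

Units are fixed throughout — mV, ms, µA/cm², mS/cm², µF/cm², mM — with no
internal conversions.  Sign convention: currents are outward-positive and
every current vanishes at its reversal potential (asserted in tests).

Key parameters (defaults in parentheses):

| parameter | meaning | default |
|---|---|---|
| C | membrane capacitance | 1 µF/cm² |
| g_NaF, g_Kdr | spike-generating conductances | 120, 100 mS/cm² |
| g_CaL | L-type calcium conductance | 0.05 mS/cm² |
| g_NaP, g_Kv12, g_CAN, g_KCa | modulatory conductances | 0 (set per experiment) |
| g_L, E_L | leak | 0.1 mS/cm², −80 mV |
| E_Na, E_Ca, E_CAN | reversals | 55, 80, 0 mV |
| K_out, K_in | K⁺ concentrations (E_K = 26.54·ln(K_out/K_in)) | 4, 140 mM |
| K_CAN, K_d | Ca half-activation of I_CAN / I_KCa | 0.74·10⁻³, 0.2·10⁻³ mM |
| f | unbound fraction of entering calcium | 0.01 |
| α | current→concentration factor, (2Fδ)⁻¹ | 5·10⁻⁴ mM·cm²·ms⁻¹·µA⁻¹ |
| k_CICR | calcium-induced calcium release gain | 0.096 ms⁻¹ |
| τ_Ca | pump clearance time constant | 10 ms |

The calcium balance is `dCa/dt = −f·α·I_CaL + k_CICR·Ca − Ca/τ_Ca`; since
CICR is linear in Ca it folds into an effective clearance constant
τ_eff = (1/τ_Ca − k_CICR)⁻¹ = 250 ms at the defaults.  k_CICR ≥ 1/τ_Ca would
make calcium grow without bound and is rejected at construction.  The α
default is reproduced to within 4 % by the unit conversion from Faraday's
constant and a 0.1 µm sub-membrane shell; the stored value is the rounded
literature constant.  E_Ca is held fixed (not Nernst-updated with Ca), and
the natural logarithm is used in E_K — the only reading consistent with a
26.54 mV coefficient (RT/F near recording temperature).  The published sweep
ranges g_Kv12 ∈ [0, 10] mS/cm² and K_out ∈ [4, 12] mM are enforced as
warnings, not errors, so parameter scans may probe their edges.

## Numerics

Integration uses an embedded Dormand–Prince 5(4) pair with proportional
step-size control, written as a numba-compiled kernel (the hysteresis sweeps
integrate minutes of simulated time per parameter point).  Defaults:
rtol 10⁻⁸, atol 10⁻¹⁰, maximum step 10 ms, dense sampling every 0.05 ms
(20 samples/ms, enough to resolve the 1–2 ms spike upstroke for peak-accurate
detection).  Dense output between accepted steps uses cubic Hermite
interpolation; with the 10 ms step cap its error is orders of magnitude
below the solver tolerance (the calcium-decay closed form is reproduced to
better than 10⁻⁶ relative on the sampled grid).  Steps never straddle a
segment boundary of the injected-current program, so waveform kinks and
jumps are hit exactly.  After each accepted step gates are clamped to [0, 1]
and calcium floored at zero (the calcium equation can transiently undershoot
numerically).  Everything is deterministic — identical inputs give
bitwise-identical traces; there is no random number generator anywhere in
the package.

A readable reference right-hand side lives in `motobist.model`; a dedicated
test holds the compiled kernel and the reference to within rounding of each
other.  The reference implementation also serves equilibrium analysis: at a
fixed point all gates sit on their steady-state curves and
Ca* = −f·α·I_CaL(V)·τ_eff, so the equilibrium problem reduces to a scalar
root search in V (0.5 mV scan grid, Brent refinement, residuals checked
below 10⁻¹⁰).  Stability is classified from the eigenvalues of a
central-difference Jacobian of the full 8-dimensional system: stable node
(no eigenvalue with positive real part), saddle (exactly one), unstable
(more than one).

## Protocols

**Ramp hysteresis.**  A symmetric triangular ramp 0 → max_I → 0 starting
from the resting state.  I_up is the injected current at the first spike
peak of the ascending phase, I_down at the last spike peak of the descending
phase.  Spikes are upward crossings of −10 mV with a 2 ms refractory period
(action potentials here overshoot 0 mV, plateaus stay below −20 mV).  The
phase duration is doubled from 5 s until both thresholds move by less than
0.02 µA/cm², with a cap of 160 s per phase.  The cap was set where the
protocol's intrinsic bias — the slow passage through the fold, which delays
the first spike past the static fold on the ascent and lets spiking linger
below the cycle's end on the descent — drops to ~0.04 µA/cm², below the
0.05 µA/cm² width used to call a cell bistable.  Parameter scans use
coarser, per-family settings chosen from the observed convergence behaviour:
the I_NaP/[K⁺]_o family stabilises within a few doublings (40 s cap, 0.05
tolerance), while the g_CAN/g_KCa family converges slowly (80 s cap, 0.02
tolerance) and additionally validates every ramp-positive cell with the step
protocol below, because near that family's threshold the capped ramp can
retain a transient width above 0.05 µA/cm² even where direct simulation
shows no limit cycle coexisting with rest.

**Step validation.**  Five plateaus 0, I_mid, I_high, I_mid, 0 (2 s each)
with I_mid at the midpoint of the candidate hysteresis interval and I_high
above I_up.  True bistability shows silence on the first intermediate
plateau and spiking on the second; each plateau is judged on its final 75 %
to skip settling transients.

**Holding ladder.**  One run per holding current: baseline, a 2 s
depolarizing pulse, a 7.5 s observation window, then a brief hyperpolarizing
test pulse (−2 µA/cm², 500 ms by default — the experimental pulse shape is
not specified, both are configurable).  A level counts as bistable when the
pre-pulse potential stays below spike threshold, firing self-sustains up to
the test pulse, and the test pulse resets the neuron to silence.

**Trace features.**  The sADP/AHP amplitude is the extremal post-stimulus
deviation from the holding potential (mean V over the 500 ms before the
pulse — the simulated analog of the experimental holding potential), the
area its time integral over the window, and the duration the time beyond
half the peak, measured on a 50 ms moving-mean smoothed trace to suppress
channel-kinetics ripple (a raw option is retained).  Firing-rate profiles
use reciprocal inter-spike intervals at ISI midpoints, a least-squares
slope, and a dead band of ±5 % of the mean rate per second to separate
ramping from adapting from flat.

## Calibrated preset baseline

The bistable-cell figure presets print only g_CAN; the cell's background
g_KCa and g_NaP are not stated.  An all-zero background cannot reproduce
the published ramp thresholds (I_up = 1.7, I_down = 1.1 µA/cm² at
g_CAN = 0.5): with nothing opposing I_CAN, the plateau sustains spiking all
the way to zero injected current (I_down = 0).  The shipped fig2-family
baseline is therefore calibrated — g_KCa = 0.2925, g_NaP = 0.03 mS/cm²,
g_Kv12 = 0, K_out = 4 mM — which reproduces (1.69, 1.09) under the converged
ramp protocol while keeping both published controls intact: removing I_CAN
or setting k_CICR = 0 collapses the width below 0.05 µA/cm².  Presets mark
printed versus assumed values separately in their provenance records.

The persistent-sodium family needs no calibration.  With g_CAN = 0,
g_KCa assumed 0: bistability at g_NaP = 0.25 emerges at [K⁺]_o = 12 mM on a
0.5 mM grid; the minimal [K⁺]_o over g_NaP < 0.5 is 11 mM; at g_NaP = 0.4
and [K⁺]_o = 12 the hysteresis interval is (0.39, 0.86) µA/cm²; and the
g_NaP threshold at 12 mM falls between 0.15 and 0.25 mS/cm² — all in line
with the published maps.  The resting branch of this regime lies below the
limit cycle's voltage range, and spiking terminates on the descent where the
cycle meets the saddle; the offset threshold is read operationally from the
descending ramp rather than by a dedicated homoclinic continuation.

## Known limitations

- **The g_CAN threshold at g_KCa = 0.5 comes out near 0.8 mS/cm², not the
  published ≈ 1.**  The discrepancy is family-wide: at g_CAN = 0.9 with
  g_KCa = 0.5 this implementation is already bistable at [K⁺]_o = 4 mM and
  g_NaP = 0, so the published "switch on" demonstrations at that point
  (raising [K⁺]_o from 4 to 8 mM, or g_NaP from 0 to 0.45) have no "off"
  state here.  The equations and constants are implemented exactly as
  printed, the threshold-versus-g_KCa relation is linear as published
  (R² > 0.95), and the persistent-sodium family reproduces published
  thresholds quantitatively, so the offset most likely reflects an
  unprinted background difference in that figure family.  A background
  Kv1.2 conductance was probed and moves the thresholds the wrong way
  (its slow inactivation widens hysteresis).  The corresponding presets
  demonstrate the same switches at g_CAN = 0.7, just below this
  implementation's threshold, and say so in their notes.
- **Delayed excitation without rate ramping.**  With g_Kv12 = 2 alone, a
  rectangular pulse inside a narrow amplitude window produces seconds-long
  delayed excitation (first sustained spike ~9.5 s after pulse onset at
  10.5 µA/cm², versus a 10 ms passive time constant), but firing then onsets
  abruptly at ~125 Hz with a flat-to-slightly-adapting rate: the inter-spike
  potential dips below the Kv1.2 inactivation midpoint, so the inactivation
  gate recovers during firing instead of continuing to decline.  A
  progressively accelerating discharge is not observed in this
  implementation.
- Sub-0.05 µA/cm² hysteresis widths are below the protocol's resolution and
  are reported as no bistability.
- No temperature dependence, channel noise, Na⁺/K⁺ concentration dynamics,
  or dendritic compartments; pharmacology is represented only as conductance
  or gain changes (g_KCa, g_NaP, k_CICR).  No arclength continuation or
  Floquet analysis — branches are traced by quasi-static forward/backward
  sweeps; the narrow Kv1.2 bursting regime is detected but not
  characterised.
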