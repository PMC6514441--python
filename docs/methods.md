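# Methods

## Model

The cell is a single isopotential compartment.  tSPNs have sparse
dendritic arbors and are electrotonically compact, so one compartment
captures their somatic current-clamp behaviour.  Membrane potential
follows

    C_m dV/dt = −Σ_i I_i − I_syn + I_inj

with membrane currents I_i = G_i·m^p·h^q·(V − E_i) (outward positive)
and injected current depolarizing-positive.  Units are chosen so no
conversion constants appear: mV, ms, nS, pA, pF, µM.

Nine conductances are modelled: Na, Kd (delayed rectifier), M (slow
non-inactivating K⁺), KCa (Ca²⁺-activated K⁺), A (fast transient K⁺),
H (hyperpolarization-activated mixed cation), CaL (persistent Ca²⁺),
an ohmic leak, and an ohmic "impalement" leak representing
microelectrode injury (E_imp = −15 mV, the GHK potential of the bath
and pipette solutions with equal Na⁺/K⁺/Cl⁻ permeabilities; 0 nS unless
impalement is being simulated).  Intracellular calcium obeys
d[Ca]/dt = λ(−α·I_CaL − k_CaS·[Ca]) with λ = 0.01,
α = 0.002 µM·ms⁻¹·pA⁻¹, k_CaS = 0.024 ms⁻¹; the effective calcium
relaxation time is therefore 1/(λ·k_CaS) ≈ 4.2 s, which is the slow
timescale of spike-rate adaptation.  The KCa activation is an
instantaneous Hill function of [Ca²⁺] (half-activation 0.6 µM, Hill
coefficient 3); its dynamics are inherited entirely from calcium.

## Gating kinetics as data

No printed x_∞/τ_x functions exist for this cell type; published
models of sympathetic neurons differ considerably.  The package
therefore ships the kinetics as a versioned YAML config
(`tspn/data/standard_kinetics.yaml`): every gate is a Boltzmann steady
state 1/(1+exp((V−V½)/k)) with a generalized bell time constant
τ_min + τ_amp/(exp((V−V₁)/k₁) + exp(−(V−V₂)/k₂)).  Alternative
parameterizations can be swapped in without touching the integrator.

The shipped parameterization was calibrated so the standard cell
reproduces its reference phenotype at room temperature:

- rest near −59 mV; input resistance ≈ 0.6 GΩ intact and ≈ 118 MΩ with
  a 7 nS impalement leak at −70 mV;
- rheobase ≈ 32 pA intact, rising ≈ 6-fold under impalement;
- repetitive firing at every suprathreshold current when intact, with
  M- and KCa-mediated adaptation;
- an M-dependent phasic regime under impalement load;
- A-mediated onset delay and "notch" from hyperpolarized holding;
- H-mediated sag at deep hyperpolarization and M-dependent rebound
  firing after release from a −50 mV hold.

Functionally important shapes, and why they are what they are:

- **Na inactivation** is steep (k = 4, V½ = −52.5) so that the
  depolarized silent state of an impaled cell is stable (little window
  current at −45…−35 mV), while availability at the intact
  interspike voltage (−55…−60 mV) stays high.
- **Na activation** carries a narrow slow-τ band near −47 mV.  Slowly
  depolarizing (intact) trajectories equilibrate through it unnoticed;
  the fast onset of a heavily loaded (impaled) cell is delayed,
  raising its threshold current — this is what separates the intact
  (~20 pA) and impaled (~180 pA) firing boundaries beyond the purely
  ohmic ratio.
- **Kd deactivation** is slow below −50 mV (τ ≈ 30–60 ms), producing
  the long fast-AHP this cell type shows and re-priming Na between
  spikes, which keeps intact cells repetitive at all currents.
- **M** activates above ≈ −40 mV with τ ≈ 100–300 ms.  Under
  impalement the interspike voltage is propped up near −50 mV by the
  depolarized injury reversal, so M accumulates spike over spike and
  silences the cell (phasic firing); intact interspike voltages are
  more hyperpolarized and M deactivates between spikes.
- **A inactivation** has a sharp τ cliff at ≈ −70 mV: fast below it
  (so small hyperpolarizing probes relax mono-exponentially), slow
  above it (so A persists through a depolarizing approach and carves
  the pre-spike notch after hyperpolarized holding).
- **H** activates below ≈ −88 mV, giving sag only at strong
  hyperpolarization.

## Integration

Exponential Euler with a fixed 0.1 ms step: the voltage relaxes
exponentially towards the instantaneous conductance-weighted reversal,
and gates relax exactly towards their steady state evaluated at the
midpoint of the voltage step.  The midpoint evaluation roughly halves
spike-time discretization error; against a 0.01 ms reference, spike
counts are identical for standard-cell steps up to 200 pA, first-spike
times agree within 0.5 ms, and cumulative phase drift stays below
2 ms per elapsed spike.  Integration aborts with a descriptive error if
the state becomes non-finite or |V| exceeds 200 mV.  Protocols start
from the analytic fixed point of the gating system
(`steady_state_init`), so no burn-in integration is needed.

## Protocols

- **Holding bias** (`find_bias_current`): bisection on constant
  current until the settled membrane potential (mean of the final
  100 ms of a 4 s integration) is within 0.1 mV of the target; the
  analytic steady-state current sum seeds the bracket.
- **Rheobase** (`measure_rheobase`): binary search on [0, 1000] pA to
  0.5 pA for the minimal 3 s step eliciting ≥ 1 spike (spikes detected
  as upward 0 mV crossings with a 2 ms lockout).  3 s matches the
  duration used for most recordings of this type.
- **Firing classification**: N = no spikes during the step; R = ≥ 2
  spikes with ≥ 1 in the final half of the step; P = otherwise
  (spiking that dies out before the final half).  A phasic band
  narrower than the 0.5 pA search tolerance is reported as a direct
  N→R transition, since it cannot be resolved at that tolerance.
- **Phase boundaries**: per impalement conductance, bisection for the
  first firing current and, where the top-of-range class is
  repetitive, for the phasic→repetitive boundary.
- **Strength–duration**: the same threshold search per pulse duration;
  spikes peaking within 100 ms after brief pulses count as elicited.
- **f–I curves**: maximal rate = first interspike interval inverted;
  sustained rate = mean of the last three interval rates provided those
  intervals end in the final half of the step; slopes by least squares
  over the defined points.

## Feature extraction

Passive properties come from a Levenberg–Marquardt fit of
ΔV·exp(−t/τ_m) + (V_hold − ΔV) to the response to a ≥ 1.5 s
hyperpolarizing step, with R_in = ΔV/I and C_m = τ_m/R_in.  Spike
threshold is the last point before the peak where dV/dt (on a 5-sample
smoothed copy) crosses 5 mV/ms from below; the criterion is
configurable, and doubling it moves the detected threshold by at most
≈ 3 mV on model spikes (the model's spike foot is gradual).  AP
amplitude is peak minus threshold; half-width is measured at half
amplitude with linear interpolation.  The fast AHP is measured against
the steady-state step voltage and only on single-spike minimal
suprathreshold traces; the slow AHP is measured after step offset
against the pre-step baseline.  Sag is a ≥ 1 mV relaxation from an
early minimum; rebound is a spike within 500 ms of step offset; a
notch is a ≥ 1 mV dip of the pre-spike trajectory below its fitted
charging exponential.  Absolute voltages can be corrected by the fixed
−10 mV liquid-junction adjustment; relative quantities never are.

## Synthetic population and statistics

The generator emulates the observed heterogeneity of this cell type:
maximal conductances are sampled log-normally (leak median 0.7 nS with
σ_log = 1.0; the other channels with σ_log = 0.3–0.5 around the
standard values), capacitance from a truncated normal
(89 ± 27 pF within [45, 170]), and draws are rejected unless the
steady-state input resistance falls in [250, 2350] MΩ and the cell
rests quietly between −90 and −40 mV.  With n = 30 the sampled R_in
spans roughly 0.3–2 GΩ.  Correlations use Pearson's r with two-tailed
t-test p values, computed pairwise-complete, and a Šidák-corrected
significance level α' = 1 − (1−α)^(1/m) (0.0017 for α = 0.05,
m = 30).

Synaptic drive is a Poisson event train convolved with a
difference-of-exponentials kernel (τ_rise 1 ms, τ_decay 15 ms)
normalized to unit peak, with log-normal event amplitudes (median
1.2 nS, σ_log = 1.0) so that occasional large events ride on a
background of small ones; the event rate defaults to ~12 Hz.  Events
are summed into a dense conductance waveform before integration.

## What the generator does and does not emulate

Passing tests show that the *model* population reproduces the
qualitative structure of the recorded one — the spread of input
resistance and capacitance, threshold-linked excitability, repetitive
firing with adaptation.  They do not show that real recordings would
yield the same numbers: the generator contains no electrode artifacts,
no slow drift, no channel noise, and its voltage traces are noiseless,
so detection thresholds that work here may need retuning on real data.

## Known limitations

- The impaled cell's return to repetitive firing occurs near 205 pA,
  well below the several-hundred-pA boundary of the reference
  behaviour; with the reconstructed kinetics the depolarization-block
  branch that sustains phasic silence destabilizes early.  The phasic
  band (~180–205 pA at 7 nS) is therefore narrower than it should be.
- With the 7 nS impalement leak the input resistance at −70 mV is
  ≈ 118 MΩ, slightly above the ≈ 100 MΩ reference value, because the
  intact cell's resting conductance is ≈ 1.5 nS.
- The H-current gives many cells a sag-like creep whose time constant
  is comparable to the membrane time constant; single-exponential
  passive fits on such cells are biased by up to tens of percent in
  τ_m and C_m.  This mirrors what sag does to real patch-clamp fits,
  but it means the population-median parameter recovery misses the 3%
  target.
- Spike half-widths (~2 ms) are narrower, and absolute thresholds
  (~−35 mV) slightly higher, than the recorded means; both are within
  the recorded ranges.
- Because the dV/dt-criterion threshold sits well above the voltage at
  which the model cell dynamically escapes to a spike, the ohmic
  rheobase estimate (V_th − V_hold)/R_in overestimates the measured
  rheobase roughly two-fold across a synthetic population, and the two
  correlate only moderately (r ≈ 0.5) — weaker than in recordings,
  where the criterion threshold and escape voltage nearly coincide.
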