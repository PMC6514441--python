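# tspn

Conductance-based modelling of thoracic sympathetic postganglionic
neurons (tSPNs) — the paravertebral chain cells that form the final
output of the sympathetic nervous system — together with the
virtual current-clamp experiments and patch-clamp feature extraction
used to study their excitability.

tSPNs recorded with whole-cell patch pipettes turn out to be far more
excitable than decades of sharp-microelectrode work suggested: input
resistances around a gigaohm, rheobases of a few tens of picoamps, and
robust repetitive firing.  The discrepancy is explained by the
*impalement injury conductance* a sharp electrode introduces — a
non-selective leak of several nanosiemens with a reversal near −15 mV.
This package implements a single-compartment model of the tSPN and the
protocols needed to explore that explanation quantitatively.

## The model

Membrane potential obeys

    C_m dV/dt = −Σ_i I_i − I_syn + I_inj ,        I_i = G_i m^p h^q (V − E_i)

with Hodgkin–Huxley gating `dx/dt = (x_∞(V) − x)/τ_x(V)` and
first-order somatic calcium handling

    d[Ca²⁺]/dt = λ(−α I_CaL − k_CaS [Ca²⁺]) ,  λ = 0.01, α = 0.002 µM·ms⁻¹·pA⁻¹, k_CaS = 0.024 ms⁻¹.

The standard cell carries nine conductances (nS / mV reversal): fast
Na⁺ 300/+60, delayed-rectifier K⁺ 2000/−90, M-type K⁺ 50/−90,
Ca²⁺-activated K⁺ 50/−90, A-type K⁺ 50/−90, H-current 1/−32,
persistent L-type Ca²⁺ 1.2/+120, ohmic leak 1/−55, and an impalement
leak (0 nS unless simulating microelectrode injury) with E_imp = −15 mV
— the Goldman–Hodgkin–Katz potential of the recording solutions at
equal Na⁺/K⁺/Cl⁻ permeabilities.  Gating kinetics live in a versioned
YAML config (`tspn/data/standard_kinetics.yaml`); they are data, not
code.  Integration is exponential-Euler at dt = 0.1 ms.

## Worked example

```python
import tspn
from tspn import protocols

cell = tspn.standard_cell()
protocols.measure_rheobase(cell, hold_v=-70.0)        # 31.74 pA
protocols.model_input_resistance(cell, -70.0)         # 587 MOhm

impaled = tspn.with_impalement(cell, 7.0)             # 7 nS injury leak
protocols.model_input_resistance(impaled, -70.0)      # 117.9 MOhm
protocols.measure_rheobase(impaled, hold_v=-70.0)     # 192.9 pA  (~6.1-fold)

pd = protocols.phase_boundaries(tspn.preset("fig5"), [0.0, 7.0])
pd.n_to_r[0]    # 20.5 pA  : intact cell jumps straight to repetitive firing
pd.n_to_p[1]    # 180.8 pA : impaled cell is silent below ~180 pA, then phasic
```

The same experiments are available from the shell:

    tspn rheobase --preset standard
    tspn rheobase --preset standard --gimp 7
    tspn phase-diagram --preset fig5 --gimp-range 0:10:1
    tspn simulate --preset fig4 --step-pa 90 --out step.tsv
    tspn features --in step.tsv

Reading of the numbers above: a 7 nS impalement leak drops the input
resistance five-fold, raises the threshold current six-fold, and — in
combination with the M-current — converts repetitive firing into a
transient, phasic response.  Knocking the M-conductance out
(`protocols.knockout(cell, "M")`) abolishes phasic firing entirely.

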