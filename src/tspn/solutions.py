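"""Ionic composition of the recording solutions (mM).

Totals per ion are assembled from the bath (ACSF) and pipette recipes
used for the whole-cell recordings this model is calibrated against:

ACSF: 127.99 NaCl, 1.90 KCl, 1.30 MgSO4, 2.40 CaCl2, 1.20 KH2PO4,
9.99 glucose, 26.04 NaHCO3.
Pipette: 140.0 K-gluconate, 11.0 EGTA, 10 HEPES, 1.32 CaCl2 (the small,
unquantified K+ added as KOH for pH adjustment is ignored; K+ is taken
at its nominal 140 mM).

Only the three major permeant species (Na+, K+, Cl-) are tabulated, as
needed by the Nernst and Goldman-Hodgkin-Katz calculations.
"""

#: Extracellular (bath) concentrations, mM.
ACSF = {
    "Na": 127.99 + 26.04,
    "K": 1.90 + 1.20,
    "Cl": 127.99 + 1.90 + 2 * 2.40,
}

#: Intracellular (pipette) concentrations, mM.
PIPETTE = {
    "Na": 0.0,
    "K": 140.0,
    "Cl": 2 * 1.32,
}
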