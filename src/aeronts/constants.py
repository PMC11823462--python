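"""Physical constants used throughout the pipeline.

All masses are monoisotopic and given in Da. Ion <-> neutral conversions
always use PROTON_MASS / ELECTRON_MASS from this table; no other module
defines atomic masses.
"""

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.007276466

#: Monoisotopic atomic masses (Da) of the elements considered for formula
#: assignment of water-soluble organics.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "F": 18.9984032,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
}

#: Valences used by the SENIOR feasibility test.
VALENCE: dict[str, int] = {
    "C": 4, "H": 1, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

#: Per-atom isotopologue abundance ratios relative to the monoisotopic
#: species, used for first-order M+1 / M+2 pattern prediction.
ISO_M1_RATIO: dict[str, float] = {
    "C": 0.010816,   # 13C/12C
    "H": 0.000115,   # 2H/1H
    "N": 0.003654,   # 15N/14N
    "O": 0.000381,   # 17O/16O
    "S": 0.007895,   # 33S/32S
}

ISO_M2_RATIO: dict[str, float] = {
    "O": 0.002055,   # 18O/16O
    "S": 0.044742,   # 34S/32S
    "Cl": 0.319958,  # 37Cl/35Cl
    "Br": 0.972776,  # 81Br/79Br
}

#: Canonical element order: Hill convention (C, H, then alphabetical).
HILL_ORDER = ("C", "H", "Br", "Cl", "F", "I", "N", "O", "P", "S")

CF2_MASS = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["F"]
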