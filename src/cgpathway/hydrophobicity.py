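"""Residue transfer free-energy scale used by the membrane burial term.

Default scale: Wimley–White water-to-octanol transfer free energies
(kcal/mol per residue, whole-residue values).  Negative values favour
the membrane interior.  Charged residues (Asp, Glu, Lys, Arg) carry the
charged-state values; His the neutral-imidazole value is not used —
the tabulated (charged) value is kept for consistency with the
formal-charge table, which treats His as neutral only electrostatically.
The scale is an ordinary dict and can be replaced wholesale through
``EnergyParams.hydrophobicity_scale``.
"""

WIMLEY_WHITE_OCTANOL: dict[str, float] = {
    "ALA": 0.50,
    "ARG": 1.81,
    "ASN": 0.85,
    "ASP": 3.64,
    "CYS": -0.02,
    "GLN": 0.77,
    "GLU": 3.63,
    "GLY": 1.15,
    "HIS": 2.33,
    "ILE": -1.12,
    "LEU": -1.25,
    "LYS": 2.80,
    "MET": -0.67,
    "PHE": -1.71,
    "PRO": 0.14,
    "SER": 0.46,
    "THR": 0.25,
    "TRP": -2.09,
    "TYR": -0.71,
    "VAL": -0.46,
}

#: Formal charges at neutral pH used by the screened-Coulomb term.
FORMAL_CHARGES: dict[str, float] = {
    "ASP": -1.0,
    "GLU": -1.0,
    "LYS": +1.0,
    "ARG": +1.0,
    "HIS": 0.0,
}
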