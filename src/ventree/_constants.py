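"""Physical constants shared across modules.

Monoisotopic atomic masses (CODATA/IUPAC values, Da) and nominal mercury
isotope-abundance ratios used to synthesize invertible ratio tables.
"""

# Monoisotopic masses of the neutral atoms, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Cl": 34.96885268,
    "S": 31.97207100,
}

# Mass removed when forming [M-H]-: a proton leaves, the electron stays.
PROTON_MASS = 1.00727646

# Theoretical mass-dependent fractionation slopes for capital-delta notation.
HG_BETA = {199: 0.252, 200: 0.5024, 201: 0.752}

# Nominal xxxHg/198Hg abundance ratios (IUPAC representative isotopic
# composition); only used as the reference scale for synthetic ratio tables.
HG_RATIO_198 = {
    199: 16.87 / 9.97,
    200: 23.10 / 9.97,
    201: 13.18 / 9.97,
    202: 29.86 / 9.97,
}

HG_DELTA_ISOTOPES = (199, 200, 201, 202)
HG_CAPDELTA_ISOTOPES = (199, 200, 201)
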