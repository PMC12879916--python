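"""Physical constants bundled with provenance.

Selenium isotope data are the IUPAC/CIAAW representative values
(Meija et al., Pure Appl. Chem. 88 (2016) 293, "Isotopic compositions
of the elements 2013"; atomic masses from AME2020). Amino-acid residue
masses are the standard monoisotopic/average values used in proteomics
(Unimod / ExPASy), i.e. the residue contribution inside a peptide chain;
a free peptide adds one water.
"""

from __future__ import annotations

# --- selenium ---------------------------------------------------------------

#: Natural isotopic abundances of selenium (atom fractions).
SE_NATURAL_ABUNDANCES: dict[int, float] = {
    74: 0.0089,
    76: 0.0937,
    77: 0.0763,
    78: 0.2377,
    80: 0.4961,
    82: 0.0873,
}

#: Atomic masses of the selenium isotopes, Da.
SE_ISOTOPE_MASSES: dict[int, float] = {
    74: 73.9224759,
    76: 75.9192137,
    77: 76.9199142,
    78: 77.9173095,
    80: 79.9165218,
    82: 81.9166995,
}

#: Standard atomic weight of natural selenium, g/mol.
SE_ATOMIC_WEIGHT: float = 78.971

#: Isotopes a serum speciation run monitors (quadrupole sequence order).
MONITORED_ISOTOPES: tuple[int, ...] = (74, 76, 77, 78, 80)

# --- mass spectrometry ------------------------------------------------------

PROTON_MASS: float = 1.00727646688
WATER_MONO: float = 18.0105646863
WATER_AVG: float = 18.01528

#: Monoisotopic residue masses, Da (U = selenocysteine).
RESIDUE_MONO: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
    "U": 150.95364,
}

#: Average residue masses, Da.
RESIDUE_AVG: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
    "U": 150.0379,
}

#: Bundled modification mass deltas, Da.  Carbamidomethylation is the fixed
#: iodoacetamide adduct on cysteine; dehydroalanine is the selenium-loss
#: degradation product of selenocysteine (U -> Dha, i.e. -H2Se +nothing on
#: the backbone: 150.95364 - 69.02146 = 81.93218 Da lighter).
MODIFICATIONS: dict[str, dict[str, object]] = {
    "carbamidomethyl": {"mono": 57.02146, "average": 57.0513, "applies_to": "C"},
    "dehydroalanine": {"mono": -81.93218, "average": -80.9750, "applies_to": "U"},
}
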