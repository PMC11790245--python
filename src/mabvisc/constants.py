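"""Physical constants, unit conversions and embedded residue-scale tables.

All unit conversions used anywhere in the package live here so that a unit
error is a one-line fix, not a hunt.
"""

from __future__ import annotations

from types import MappingProxyType

#: Avogadro constant, SI-exact (mol^-1).
N_AVOGADRO = 6.02214076e23

#: Default buffer viscosity for the formulation buffer (cP).
DEFAULT_BUFFER_VISCOSITY_CP = 1.13

#: Default measurement temperature (K).
DEFAULT_TEMPERATURE_K = 298.15

# --- unit conversions -------------------------------------------------------
#: 1 mL expressed in nm^3.
ML_TO_NM3 = 1.0e21
#: 1 mg/mL expressed in g/nm^3.
MG_PER_ML_TO_G_PER_NM3 = 1.0e-24
#: 1 mg/mL expressed in g/mL.
MG_PER_ML_TO_G_PER_ML = 1.0e-3
#: intrinsic viscosity: 1 mL/mg expressed in mL/g.
ML_PER_MG_TO_ML_PER_G = 1.0e3

# --- viscosity risk thresholds (cP) -----------------------------------------
#: Upper bound of the "green" (low-risk) viscosity band.
GREEN_MAX_CP = 20.0
#: Lower bound of the "red" band; also the binary acceptability threshold.
ACCEPTABLE_MAX_CP = 30.0

#: Structure-based ensemble charge at or above which a molecule is
#: classified as low viscosity risk (elementary charges).
ENS_CHARGE_LOW_RISK_MIN = 2.0

# --- Eisenberg normalized consensus hydrophobicity scale --------------------
# Eisenberg, Schwarz, Komaromy & Wall (1984) normalized consensus values,
# one per standard residue.
EISENBERG_SCALE = MappingProxyType({
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
})

#: Residues counted as hydrophobic in the hydrophobic-index numerator.
HYDROPHOBIC_RESIDUES = frozenset("ACFILPVGWY")
#: Residues counted as hydrophilic in the hydrophobic-index denominator.
#: Note M is deliberately on the hydrophilic side: the index definition
#: partitions the alphabet this way even though M scores hydrophobic on
#: the Eisenberg scale.
HYDROPHILIC_RESIDUES = frozenset("DEHKMNQRST")

# --- side-chain / terminus pKa tables ---------------------------------------
# Keyed by set name; each table maps ionizable group -> pKa. "nterm"/"cterm"
# are the free termini. Positive groups: H, K, R, nterm. Negative: D, E, C,
# Y, cterm.
PKA_TABLES = MappingProxyType({
    # EMBOSS defaults (iep program).
    "emboss": MappingProxyType({
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
        "nterm": 8.6, "cterm": 3.6,
    }),
    # Grimsley, Scholtz & Pace (2009) average intrinsic values.
    "grimsley": MappingProxyType({
        "D": 3.5, "E": 4.2, "C": 6.8, "Y": 10.3,
        "H": 6.6, "K": 10.5, "R": 12.04,
        "nterm": 7.7, "cterm": 3.3,
    }),
})

DEFAULT_PKA_SET = "emboss"

#: Default pH at which Fv charges are evaluated (formulation pH).
DEFAULT_CHARGE_PH = 6.0

ACIDIC_GROUPS = frozenset("DECY")
BASIC_GROUPS = frozenset("HKR")

VALID_RESIDUES = frozenset(EISENBERG_SCALE)
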