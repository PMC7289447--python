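"""Physical constants, residue classifications and atom parameters.

Internal units are nm for lengths, kJ/mol for energies and K for
temperature throughout the package; PDB files (in Angstrom) are converted
on read/write.
"""

from __future__ import annotations

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083144621

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 310.0

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Positively / negatively charged side chains (His treated as uncharged
#: at physiological pH; configurable in the functions that use these).
POSITIVE_RESIDUES = {"ARG", "LYS"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}

#: Hydrophobic residue set used for buried-surface analysis.  Gly excluded
#: (no side chain); configurable at call sites.
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

#: Charged side-chain groups: residue -> (sign, atom names forming the group).
#: COM of these atoms defines the charge-group position for ion pairs.
CHARGED_GROUPS = {
    "ARG": (+1, ("NE", "CZ", "NH1", "NH2")),
    "LYS": (+1, ("NZ",)),
    "ASP": (-1, ("CG", "OD1", "OD2")),
    "GLU": (-1, ("CD", "OE1", "OE2")),
}

#: Atomic masses (Da) for COM computations.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

#: Bondi-type van der Waals radii in nm, used by the SASA quadrature.
VDW_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "SE": 0.190,
}

#: Fallback radius (nm) for elements missing from the table.
DEFAULT_VDW_RADIUS_NM = 0.170

#: Solvent probe radius (nm) for SASA.
PROBE_RADIUS_NM = 0.14
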