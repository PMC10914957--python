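"""Chemical reference data: element masses, residue tables, group inference.

All tables here are deliberately small -- the toolkit works on reduced
representations (full backbone + pseudo side chains for peptides, few-site
pseudo-lipids) and only needs masses, element classes and donor/acceptor
chemistry to be self-consistent between the generators and the analysers.
"""

from __future__ import annotations

# 40-residue amyloid-beta peptide, the default sequence for generators.
ABETA40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"

ELEMENT_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

# Average side-chain masses (residue mass minus the backbone unit), amu.
SIDECHAIN_MASS = {
    "GLY": 1.008, "ALA": 15.035, "ARG": 100.143, "ASN": 58.060,
    "ASP": 59.044, "CYS": 47.095, "GLU": 73.071, "GLN": 72.087,
    "HIS": 81.098, "ILE": 57.116, "LEU": 57.116, "LYS": 72.129,
    "MET": 75.149, "PHE": 91.133, "PRO": 41.072, "SER": 31.034,
    "THR": 45.061, "TRP": 130.170, "TYR": 107.132, "VAL": 43.089,
}

# Explicit side-chain interaction sites carried by the reduced peptide model:
# (atom_name, element, parent_heavy_or_None). Hydrogens name their parent so
# donor pairs can be resolved without coordinates.
SIDECHAIN_SITES = {
    "ARG": [("NE", "N", None), ("HE", "H", "NE"),
            ("NH1", "N", None), ("HH11", "H", "NH1"), ("HH12", "H", "NH1"),
            ("NH2", "N", None), ("HH21", "H", "NH2"), ("HH22", "H", "NH2")],
    "LYS": [("NZ", "N", None), ("HZ1", "H", "NZ"), ("HZ2", "H", "NZ"),
            ("HZ3", "H", "NZ")],
    "ASP": [("OD1", "O", None), ("OD2", "O", None)],
    "GLU": [("OE1", "O", None), ("OE2", "O", None)],
    "ASN": [("OD1", "O", None), ("ND2", "N", None),
            ("HD21", "H", "ND2"), ("HD22", "H", "ND2")],
    "GLN": [("OE1", "O", None), ("NE2", "N", None),
            ("HE21", "H", "NE2"), ("HE22", "H", "NE2")],
    "HIS": [("ND1", "N", None), ("NE2", "N", None), ("HE2", "H", "NE2")],
    "SER": [("OG", "O", None), ("HG", "H", "OG")],
    "THR": [("OG1", "O", None), ("HG1", "H", "OG1")],
    "TYR": [("OH", "O", None), ("HH", "H", "OH")],
    "TRP": [("NE1", "N", None), ("HE1", "H", "NE1")],
    "MET": [("SD", "S", None)],
}

# Residue-name based group inference.  Aliases cover the common CHARMM /
# GROMACS spellings; anything else is an explicit error upstream.
PEPTIDE_RESNAMES = set(AA_3TO1)
LIPID_RESNAME_TO_GROUP = {
    "POPC": "lipid_POPC",
    "POPS": "lipid_POPS",
    "CHOL": "lipid_CHOL",
    "CHL1": "lipid_CHOL",
}
WATER_RESNAMES = {"TIP3", "HOH", "SOL", "WAT", "SPC", "TIP4"}
ION_RESNAMES = {"NA", "CL", "SOD", "CLA", "POT", "K", "MG", "CA2"}


def infer_group(residue_name: str) -> str:
    """Map a residue name onto one of the six atom groups.

    Raises ``KeyError`` with the offending name if it is not recognised.
    """
    name = residue_name.upper()
    if name in PEPTIDE_RESNAMES:
        return "peptide"
    if name in LIPID_RESNAME_TO_GROUP:
        return LIPID_RESNAME_TO_GROUP[name]
    if name in WATER_RESNAMES:
        return "water"
    if name in ION_RESNAMES:
        return "ion"
    raise KeyError(
        f"cannot infer atom group for residue name {residue_name!r}; "
        "known names are amino acids, POPC/POPS/CHOL(CHL1), water and ions"
    )


def element_from_name(atom_name: str) -> str:
    """Best-effort element guess from an atom name (used when a file lacks
    element columns)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first in ELEMENT_MASS:
        return first
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
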