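"""Residue chemistry tables: amino-acid codes and torsion templates.

Side-chain χ definitions follow the standard heavy-atom convention
(χ1 = N–CA–CB–XG and onwards); nucleotide backbone torsions use the
canonical α…ζ naming plus the glycosidic χ.  8-oxoguanine-containing
nucleotides (8OG and friends) are treated as purines.
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS = frozenset(AA3_TO_1)

WATER_NAMES_DEFAULT = frozenset({"HOH", "WAT", "TIP3", "SOL"})
ION_NAMES_DEFAULT = frozenset({"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "CA2", "ZN"})

PURINES = frozenset({"A", "G", "DA", "DG", "8OG", "OGG", "GUN"})
PYRIMIDINES = frozenset({"C", "T", "U", "DC", "DT", "DU"})
NUCLEOTIDES = PURINES | PYRIMIDINES

#: heavy-atom side-chain torsion quadruples, all atoms within the residue
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

#: atoms kept when a side chain is truncated to Cβ for downstream rebuilding
BACKBONE_KEEP = frozenset({"N", "CA", "C", "O", "CB", "OXT", "H", "HA",
                           "H1", "H2", "H3", "HA2", "HA3"})


def glycosidic_atoms(res_name: str) -> tuple[str, str, str, str]:
    if res_name in PURINES:
        return ("O4'", "C1'", "N9", "C4")
    if res_name in PYRIMIDINES:
        return ("O4'", "C1'", "N1", "C2")
    raise KeyError(f"{res_name} is not a known nucleotide")


def is_amino_acid(res_name: str) -> bool:
    return res_name in AMINO_ACIDS


def is_nucleotide(res_name: str) -> bool:
    return res_name in NUCLEOTIDES
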