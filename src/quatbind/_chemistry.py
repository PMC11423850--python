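"""Residue dictionaries, element tables and van der Waals radii.

Small static tables shared across modules.  Radii are Bondi (1964) values
with a 1.70 Å fallback for elements outside the table.
"""

from __future__ import annotations

# 20 standard amino acids (3-letter codes)
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

DNA_RES = {"DA", "DC", "DG", "DT", "DU", "DI"}
RNA_RES = {"A", "C", "G", "U", "I"}
NUCLEOTIDE_RES = DNA_RES | RNA_RES

WATER_RES = {"HOH", "DOD", "WAT"}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

NT_TO1 = {
    "DA": "a", "DC": "c", "DG": "g", "DT": "t", "DU": "u", "DI": "i",
    "A": "a", "C": "c", "G": "g", "U": "u", "I": "i",
}

# Chemical component IDs treated as metal ions when they occur as
# single-atom non-polymer groups.  Halides and other single-atom species
# outside this set are classified as small molecules.
METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
    "SC", "TI", "V", "CR", "MN", "FE", "CO", "NI", "CU", "ZN",
    "Y", "ZR", "MO", "RU", "RH", "PD", "AG", "CD", "W", "RE",
    "OS", "IR", "PT", "AU", "HG", "AL", "GA", "IN", "SN", "TL", "PB",
}

# Bondi (1964) van der Waals radii, Å.
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "HE": 1.40, "NE": 1.54, "AR": 1.88, "KR": 2.02, "XE": 2.16,
    "LI": 1.82, "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31,
    "ZN": 1.39, "CU": 1.40, "NI": 1.63, "PD": 1.63, "PT": 1.75,
    "AG": 1.72, "AU": 1.66, "CD": 1.58, "HG": 1.55, "SE": 1.90,
    "SI": 2.10, "SN": 2.17, "TL": 1.96, "PB": 2.02, "GA": 1.87,
    "IN": 1.93, "U": 1.86,
}

DEFAULT_VDW_RADIUS = 1.70


def one_letter(comp_id: str) -> str:
    """Map a 3-letter component ID to a one-letter code ('X' if unknown)."""
    comp_id = comp_id.upper()
    if comp_id in AA_3TO1:
        return AA_3TO1[comp_id]
    if comp_id in NT_TO1:
        return NT_TO1[comp_id]
    return "X"
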