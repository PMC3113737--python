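"""Canonical amino-acid alphabet shared by all matrices and reports.

Every 20-vector in the package (propensities, PSSM columns, counts) is
ordered by :data:`AA_ORDER`.  Profiles read from external files are
re-ordered to this alphabet on load.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

UNKNOWN = "X"
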