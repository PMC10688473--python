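"""Shared constants: class order, amino-acid tables, element parameters."""

# Fixed class order used everywhere probabilities or confusion matrices appear.
CLASS_ORDER = ("GOF", "LOF", "NEUTRAL")

AMINO_ACIDS_3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Theoretical maximum accessible surface area per residue (Tien et al. 2013,
# "theoretical" column), in squared Angstroms.  Used to normalize SASA to RSA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_ASA = 197.0  # fallback for non-standard residue names

# Van der Waals radii (Angstrom) for the Shrake-Rupley solvent accessibility
# calculation; the default covers elements outside the table.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW_RADIUS = 1.70

# Standard atomic masses for center-of-mass computation.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971,
}
DEFAULT_ATOMIC_MASS = 12.0

# Residue burial threshold: relative solvent accessibility strictly below
# this value classifies a residue as buried.
BURIED_RSA_THRESHOLD = 0.20
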