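"""Chemical nomenclature tables.

Canonical PDB chemical-component atom names for the nucleotides handled by
the toolkit (ATP, ADP, GTP, GDP, UTP, UDP and their non-hydrolyzable imido
analogs), amino-acid codes, element radii and metal recognition.

Atom-name conventions follow PDB v3 (primed ribose atoms written with an
ASCII apostrophe, e.g. ``O5'``; phosphate tail ``PA``/``PB``/``PG`` with
oxygens ``O1A`` ... ``O3G``).  The imido analogs replace one bridging
oxygen with nitrogen: ``N3B`` (beta,gamma-imido triphosphate, AMP-PNP-like)
or ``N3A`` (alpha,beta-imido diphosphate, AMP-NP-like).
"""

from __future__ import annotations

# --- amino acids -----------------------------------------------------------

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

WATER_CODES = {"HOH", "WAT", "DOD"}

# Elements recognized as isolated metal cofactors (single-atom residues).
METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE",
    "CO", "NI", "CU", "ZN", "CD", "HG", "AL",
}

# --- nucleotide atom names -------------------------------------------------

RIBOSE_ATOMS = ["C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"]
RIBOSE_RING = ["O4'", "C1'", "C2'", "C3'", "C4'"]

# Phosphate tail, alpha-to-gamma.  O3A bridges PA-PB, O3B bridges PB-PG
# (terminal O3B on diphosphates).
PHOSPHATE_TRI = ["PA", "O1A", "O2A", "O3A", "PB", "O1B", "O2B", "O3B",
                 "PG", "O1G", "O2G", "O3G", "O5'"]
PHOSPHATE_DI = ["PA", "O1A", "O2A", "O3A", "PB", "O1B", "O2B", "O3B", "O5'"]

PURINE_RING = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
PYRIMIDINE_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]

BASE_ATOMS = {
    "A": PURINE_RING + ["N6"],
    "G": PURINE_RING + ["O6", "N2"],
    "U": PYRIMIDINE_RING + ["O2", "O4"],
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "U": "N1"}

#: heavy-atom composition of each true nucleotide component
NUCLEOTIDE_ATOMS = {
    "ATP": PHOSPHATE_TRI + RIBOSE_ATOMS + BASE_ATOMS["A"],
    "GTP": PHOSPHATE_TRI + RIBOSE_ATOMS + BASE_ATOMS["G"],
    "UTP": PHOSPHATE_TRI + RIBOSE_ATOMS + BASE_ATOMS["U"],
    "ADP": PHOSPHATE_DI + RIBOSE_ATOMS + BASE_ATOMS["A"],
    "GDP": PHOSPHATE_DI + RIBOSE_ATOMS + BASE_ATOMS["G"],
    "UDP": PHOSPHATE_DI + RIBOSE_ATOMS + BASE_ATOMS["U"],
}

#: analog component codes -> (true substrate, bridging nitrogen)
ANALOG_COMPONENTS = {
    "ANP": ("ATP", "N3B"),   # AMP-PNP, beta,gamma-imido
    "GNP": ("GTP", "N3B"),   # GMP-PNP
    "UNP": ("UTP", "N3B"),   # UMP-PNP-like
    "APN": ("ADP", "N3A"),   # AMP-NP, alpha,beta-imido
}

#: bridging nitrogen -> oxygen it replaces
BRIDGE_TO_OXYGEN = {"N3B": "O3B", "N3A": "O3A"}
OXYGEN_TO_BRIDGE = {v: k for k, v in BRIDGE_TO_OXYGEN.items()}

#: phosphate-group letter of every tail atom (bridge atoms belong to the
#: higher group by convention; used for the distinct-group bidentate rule)
PHOSPHATE_GROUP = {}
for _name in PHOSPHATE_TRI + ["N3A", "N3B"]:
    if _name == "O5'":
        continue
    PHOSPHATE_GROUP[_name] = _name[-1]

# --- element properties ----------------------------------------------------

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "CA": 2.31, "MG": 1.73, "ZN": 1.39, "MN": 2.05, "NA": 2.27, "K": 2.75,
    "FE": 2.05, "CO": 2.00, "NI": 1.97, "CU": 1.96, "CD": 1.58, "SR": 2.49,
}

DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def base_letter(comp_id: str, atom_names) -> str | None:
    """Infer nucleobase type (A/G/U) from component code or atom content."""
    comp = comp_id.upper()
    if comp in NUCLEOTIDE_ATOMS:
        return comp[0]
    if comp in ANALOG_COMPONENTS:
        return ANALOG_COMPONENTS[comp][0][0]
    names = set(atom_names)
    if "N9" in names:  # purine
        if "N6" in names:
            return "A"
        if "O6" in names or "N2" in names:
            return "G"
        return "A"
    if "N1" in names and "O2" in names:
        return "U"
    return None


def substrate_code(base: str, n_phosphates: int) -> str:
    """True-nucleotide component code for a base letter and phosphate count."""
    suffix = {3: "TP", 2: "DP", 1: "MP"}[n_phosphates]
    return base + suffix
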