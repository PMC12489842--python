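"""Geometric validation of NTPDase-nucleotide complexes.

A "productive" complex is recognized by a small set of features conserved
across the experimentally solved enzyme-substrate structures:

1. bidentate coordination of the metal cofactor by phosphate oxygens from
   two distinct phosphate groups;
2. symmetric placement of the cofactor between the DXG-motif aspartates of
   the first and fourth apyrase conserved regions (ACR1/ACR4), measured
   from each aspartate's C-gamma;
3. four waters in the cofactor's first hydration shell plus a catalytic
   water and one more near the last phosphate group;
4. the nucleoside geometry: ribose pucker (pseudorotation analysis) and
   the anti glycosidic configuration.

On top of the checklist, the classifier decides between the canonical
linear-like substrate conformation, the alternative mode in which the
phosphate/ribose moiety still aligns but the nucleobase is rotated away
by roughly 90 degrees, and a nonproductive pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nomenclature as nom
from .errors import AnnotationError, DataError, GeometryError, InputError
from .geometry import dihedral, plane_normal
from .ligands import (
    GraftedComplex,
    NucleotideLigand,
    SiteWaters,
    identify_components,
    select_site_waters,
)
from .structures import Atom, Residue, Selector, Structure, select_atoms
from .superpose import map_common_atoms, substrate_rmsd, superpose_structures

__all__ = [
    "CanonicalReference",
    "PuckerResult",
    "ChiResult",
    "BidentateReport",
    "MotifAnnotation",
    "ValidationReport",
    "ClosedStateReport",
    "check_bidentate",
    "find_dxg_motifs",
    "dxg_distances",
    "hydration_shell_count",
    "detect_hbonds",
    "steric_clashes",
    "ribose_pucker",
    "glycosidic_chi",
    "base_plane_angle",
    "classify_binding_mode",
    "validate_closed_state",
]


# --- result containers ------------------------------------------------------

@dataclass(frozen=True)
class CanonicalReference:
    """The benchmark NTP and NDP ligands, each in its own protein frame."""

    ntp_reference: NucleotideLigand
    ndp_reference: NucleotideLigand

    def for_substrate(self, substrate: NucleotideLigand) -> NucleotideLigand:
        if substrate.n_phosphates == 3:
            return self.ntp_reference
        if substrate.n_phosphates == 2:
            return self.ndp_reference
        raise InputError(
            f"substrate has {substrate.n_phosphates} phosphates; no matching "
            "reference (need 2 or 3)")


@dataclass
class PuckerResult:
    P: float          # pseudorotation phase, degrees in [0, 360)
    tau_m: float      # puckering amplitude, degrees
    cls: str          # C2'-endo | C3'-endo | other


@dataclass
class ChiResult:
    chi: float        # glycosidic torsion, degrees in (-180, 180]
    cls: str          # anti | syn


@dataclass
class BidentateReport:
    bidentate: bool
    contacts: list[tuple[str, float]]  # (oxygen name, distance to cofactor)
    groups: list[str]                  # distinct phosphate groups involved


@dataclass
class MotifAnnotation:
    dxg_asp: tuple[Residue, Residue]   # ACR1 aspartate first, ACR4 second
    acr_regions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class HBond:
    donor: str
    acceptor: str
    distance: float


@dataclass
class Clash:
    atom_a: str
    atom_b: str
    distance: float
    limit: float


@dataclass
class ValidationReport:
    substrate_rmsd_vs_reference: float | None
    phosphate_ribose_rmsd: float | None
    bidentate: BidentateReport | None
    dxg_distances: tuple[float, float] | None
    shell_water_count: int
    catalytic_water_present: bool
    terminal_water_present: bool
    hbonds: list[HBond]
    clashes: list[Clash]
    pucker: PuckerResult | None
    chi: ChiResult | None
    base_plane_angle_vs_reference: float | None
    mode: str                          # canonical | alternative | nonproductive
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "mode": self.mode,
            "substrate_rmsd_vs_reference": self.substrate_rmsd_vs_reference,
            "phosphate_ribose_rmsd": self.phosphate_ribose_rmsd,
            "bidentate": None if self.bidentate is None else {
                "bidentate": self.bidentate.bidentate,
                "contacts": self.bidentate.contacts,
                "groups": self.bidentate.groups,
            },
            "dxg_distances": self.dxg_distances,
            "shell_water_count": self.shell_water_count,
            "catalytic_water_present": self.catalytic_water_present,
            "terminal_water_present": self.terminal_water_present,
            "n_hbonds": len(self.hbonds),
            "hbonds": [[h.donor, h.acceptor, round(h.distance, 3)] for h in self.hbonds],
            "n_clashes": len(self.clashes),
            "clashes": [[c.atom_a, c.atom_b, round(c.distance, 3)] for c in self.clashes],
            "pucker": None if self.pucker is None else {
                "P": self.pucker.P, "tau_m": self.pucker.tau_m, "cls": self.pucker.cls},
            "chi": None if self.chi is None else {
                "chi": self.chi.chi, "cls": self.chi.cls},
            "base_plane_angle_vs_reference": self.base_plane_angle_vs_reference,
            "warnings": self.warnings,
        }


@dataclass
class ClosedStateReport:
    ca_rmsd: float
    asp_asp_distance: float
    template_asp_asp_distance: float
    margin: float
    closed: bool


# --- component plumbing -----------------------------------------------------

def _components(complex_like) -> tuple[Structure, NucleotideLigand, Atom | None, SiteWaters]:
    if isinstance(complex_like, GraftedComplex):
        return (complex_like.target, complex_like.substrate,
                complex_like.cofactor, complex_like.waters)
    substrate, cofactor, waters = identify_components(complex_like)
    return complex_like, substrate, cofactor, waters


# --- checklist features -----------------------------------------------------

def check_bidentate(complex_like, coord_min: float = 2.0,
                    coord_max: float = 3.0) -> BidentateReport:
    """Bidentate cofactor coordination by two distinct phosphate groups.

    True iff at least two substrate phosphate oxygens belonging to
    *different* phosphate groups (alpha/beta/gamma, by atom-name suffix)
    lie within [coord_min, coord_max] of the cofactor.
    """
    _, substrate, cofactor, _ = _components(complex_like)
    if cofactor is None:
        raise InputError("no cofactor ion in the complex")
    contacts: list[tuple[str, float]] = []
    groups: set[str] = set()
    for atom in substrate.atoms:
        if atom.element.upper() != "O":
            continue
        group = nom.PHOSPHATE_GROUP.get(atom.name)
        if group is None:
            continue
        d = float(np.linalg.norm(atom.coord - cofactor.coord))
        if coord_min <= d <= coord_max:
            contacts.append((atom.name, round(d, 3)))
            groups.add(group)
    return BidentateReport(bidentate=len(groups) >= 2,
                           contacts=sorted(contacts, key=lambda t: t[1]),
                           groups=sorted(groups))


def find_dxg_motifs(structure: Structure, cofactor: Atom,
                    radius: float = 6.0,
                    override: tuple[int, int] | None = None) -> MotifAnnotation:
    """Locate the two cofactor-coordinating DXG (Asp-x-Gly) aspartates.

    Scans each polymer chain for the Asp-x-Gly pattern and keeps aspartates
    whose C-gamma lies within ``radius`` of the cofactor; the two nearest
    are returned in sequence order (ACR1 first).  ``override`` skips the
    pattern search and takes explicit residue numbers instead.
    """
    candidates: list[tuple[float, Residue]] = []
    for chain_name, residues in structure.chains.items():
        poly = [r for r in residues if r.is_polymer]
        for i, res in enumerate(poly):
            if override is not None:
                if res.comp_id == "ASP" and res.seq_id in override:
                    cg = res.get("CG")
                    if cg is None:
                        raise DataError(f"ASP {res.seq_id} has no CG atom")
                    candidates.append((float(np.linalg.norm(cg.coord - cofactor.coord)),
                                       res))
                continue
            if res.comp_id != "ASP" or i + 2 >= len(poly):
                continue
            if poly[i + 2].comp_id != "GLY":
                continue
            # pattern residues must be sequence-contiguous
            if poly[i + 2].seq_id - res.seq_id != 2:
                continue
            cg = res.get("CG")
            if cg is None:
                continue
            d = float(np.linalg.norm(cg.coord - cofactor.coord))
            if d <= radius:
                candidates.append((d, res))
    if len(candidates) < 2:
        raise AnnotationError(
            f"found {len(candidates)} DXG aspartate(s) near the cofactor; "
            "two are required - consider an explicit residue override")
    nearest = sorted(candidates, key=lambda t: t[0])[:2]
    pair = sorted((res for _, res in nearest), key=lambda r: r.seq_id)
    return MotifAnnotation(dxg_asp=(pair[0], pair[1]))


def dxg_distances(structure: Structure, motifs: MotifAnnotation,
                  cofactor: Atom) -> tuple[float, float]:
    """C-gamma -> cofactor distances of the two DXG aspartates (ACR1, ACR4)."""
    out = []
    for res in motifs.dxg_asp:
        cg = res.get("CG")
        if cg is None:
            raise DataError(f"ASP {res.seq_id} has no CG atom")
        out.append(float(np.linalg.norm(cg.coord - cofactor.coord)))
    return out[0], out[1]


def hydration_shell_count(structure: Structure, cofactor: Atom,
                          cutoff: float = 3.2) -> tuple[int, list[Residue]]:
    """Count water oxygens within ``cutoff`` of the cofactor."""
    found = []
    for _, res in structure.residues():
        if not res.is_water:
            continue
        for atom in res.atoms:
            if atom.element.upper() == "O" and \
                    float(np.linalg.norm(atom.coord - cofactor.coord)) <= cutoff:
                found.append(res)
                break
    return len(found), found


# --- contacts ---------------------------------------------------------------

def _atom_records(structure: Structure):
    for chain_name, res in structure.residues():
        for atom in res.atoms:
            yield chain_name, res, atom


def _label(chain: str, res: Residue, atom: Atom) -> str:
    return f"{chain}/{res.comp_id}{res.seq_id}/{atom.name}"


def _backbone_adjacent(chain_a: str, res_a: Residue, atom_a: Atom,
                       chain_b: str, res_b: Residue, atom_b: Atom) -> bool:
    backbone = {"N", "CA", "C", "O"}
    return (chain_a == chain_b
            and abs(res_a.seq_id - res_b.seq_id) == 1
            and atom_a.name in backbone and atom_b.name in backbone)


def detect_hbonds(complex_like, d_max: float = 3.5, ang_min: float = 120.0,
                  d_min: float = 2.2) -> list[HBond]:
    """Geometric hydrogen-bond detection between heavy atoms.

    Pairs of N/O atoms from different residues with distance in
    [d_min, d_max] count as contacts.  When explicit hydrogens exist on the
    donor, the D-H...A angle must also reach ``ang_min``; the crystal-derived
    inputs carry no hydrogens, so the distance criterion usually decides.
    Covalently adjacent backbone pairs are excluded.
    """
    structure = complex_like.target if isinstance(complex_like, GraftedComplex) \
        else complex_like
    records = [(c, r, a) for c, r, a in _atom_records(structure)
               if a.element.upper() in ("N", "O")]
    hydrogens: dict[int, list[Atom]] = {}
    for _, res, atom in _atom_records(structure):
        if atom.element.upper() == "H":
            # attach to nearest heavy atom in the same residue
            heavies = [a for a in res.atoms if a.element.upper() != "H"]
            if heavies:
                host = min(heavies,
                           key=lambda a: float(np.linalg.norm(a.coord - atom.coord)))
                hydrogens.setdefault(id(host), []).append(atom)
    out: list[HBond] = []
    for i in range(len(records)):
        chain_i, res_i, atom_i = records[i]
        for j in range(i + 1, len(records)):
            chain_j, res_j, atom_j = records[j]
            if res_i is res_j:
                continue
            if _backbone_adjacent(chain_i, res_i, atom_i, chain_j, res_j, atom_j):
                continue
            d = float(np.linalg.norm(atom_i.coord - atom_j.coord))
            if not d_min <= d <= d_max:
                continue
            ok = True
            for donor, acceptor in ((atom_i, atom_j), (atom_j, atom_i)):
                for h in hydrogens.get(id(donor), []):
                    u = donor.coord - h.coord
                    v = acceptor.coord - h.coord
                    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < ang_min:
                        ok = False
            if ok:
                out.append(HBond(_label(chain_i, res_i, atom_i),
                                 _label(chain_j, res_j, atom_j), d))
    out.sort(key=lambda h: (h.distance, h.donor, h.acceptor))
    return out


def steric_clashes(complex_like, overlap_factor: float = 0.6) -> list[Clash]:
    """van der Waals overlap detection.

    Reports pairs of atoms from different residues closer than
    ``overlap_factor`` times the sum of their element vdW radii.  Pairs
    within one residue (which covers the substrate's own 1-2/1-3 bonded
    neighborhood, the substrate being a single residue) and covalently
    adjacent backbone pairs are excluded.
    """
    structure = complex_like.target if isinstance(complex_like, GraftedComplex) \
        else complex_like
    records = [(c, r, a) for c, r, a in _atom_records(structure)
               if a.element.upper() != "H"]
    coords = np.array([a.coord for _, _, a in records])
    radii = np.array([nom.vdw_radius(a.element) for _, _, a in records])
    out: list[Clash] = []
    n = len(records)
    for i in range(n):
        chain_i, res_i, atom_i = records[i]
        diffs = coords[i + 1:] - coords[i]
        dists = np.linalg.norm(diffs, axis=1)
        limits = overlap_factor * (radii[i] + radii[i + 1:])
        for off in np.nonzero(dists < limits)[0]:
            j = i + 1 + int(off)
            chain_j, res_j, atom_j = records[j]
            if res_i is res_j:
                continue
            if _backbone_adjacent(chain_i, res_i, atom_i, chain_j, res_j, atom_j):
                continue
            if chain_i == chain_j and abs(res_i.seq_id - res_j.seq_id) == 1 \
                    and {atom_i.name, atom_j.name} & {"C", "N"} \
                    and atom_i.name in ("C", "N", "CA", "O", "CB") \
                    and atom_j.name in ("C", "N", "CA", "O", "CB"):
                continue  # peptide-link neighborhood
            out.append(Clash(_label(chain_i, res_i, atom_i),
                             _label(chain_j, res_j, atom_j),
                             float(dists[off]), float(limits[off])))
    out.sort(key=lambda c: (c.distance, c.atom_a, c.atom_b))
    return out


# --- nucleoside geometry ----------------------------------------------------

_NU_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),   # nu0
    ("O4'", "C1'", "C2'", "C3'"),   # nu1
    ("C1'", "C2'", "C3'", "C4'"),   # nu2
    ("C2'", "C3'", "C4'", "O4'"),   # nu3
    ("C3'", "C4'", "O4'", "C1'"),   # nu4
]


def ring_torsions(ligand: NucleotideLigand) -> np.ndarray:
    """The five endocyclic ribose torsions nu0..nu4 in degrees."""
    missing = [n for n in nom.RIBOSE_RING if ligand.get(n) is None]
    if missing:
        raise DataError(f"ribose ring atoms missing: {missing}")
    out = []
    for quad in _NU_ATOMS:
        coords = [ligand.get(n).coord for n in quad]
        out.append(dihedral(*coords))
    return np.array(out)


def pseudorotation_from_torsions(nu: Sequence[float]) -> tuple[float, float]:
    """Pseudorotation phase P and amplitude tau_m from nu0..nu4.

    Exact least-squares solution of the pseudorotation cosine model
    nu_j = tau_m cos(P + 144 (j - 2)): writing the model as a linear
    combination of cos/sin basis torsions gives a = (2/5) sum nu_j c_j and
    b = -(2/5) sum nu_j s_j with P = atan2(b, a), tau_m = hypot(a, b).
    For torsions that follow the model exactly this coincides with the
    classic two-term phase formula; for real (slightly anharmonic) rings it
    is the best-fit phase.  P is folded into [0, 360), tau_m >= 0.
    """
    nu = np.asarray(nu, dtype=float)
    j = np.arange(5)
    arg = np.radians(144.0 * (j - 2))
    a = 0.4 * float(np.sum(nu * np.cos(arg)))
    b = -0.4 * float(np.sum(nu * np.sin(arg)))
    tau_m = float(np.hypot(a, b))
    p = float(np.degrees(np.arctan2(b, a))) % 360.0
    return p, tau_m


def classify_pucker(p: float) -> str:
    if 0.0 <= p % 360.0 < 36.0:
        return "C3'-endo"
    if 144.0 <= p % 360.0 < 180.0:
        return "C2'-endo"
    return "other"


def ribose_pucker(ligand: NucleotideLigand) -> PuckerResult:
    """Sugar-pucker pseudorotation analysis of the furanose ring."""
    nu = ring_torsions(ligand)
    p, tau_m = pseudorotation_from_torsions(nu)
    return PuckerResult(P=p, tau_m=tau_m, cls=classify_pucker(p))


def glycosidic_chi(ligand: NucleotideLigand) -> ChiResult:
    """Glycosidic torsion chi and its anti/syn classification.

    Purines: O4'-C1'-N9-C4; pyrimidines: O4'-C1'-N1-C2.  The anti window
    is [90, 180] plus (-180, -90).
    """
    if ligand.is_purine:
        quad = ("O4'", "C1'", "N9", "C4")
    else:
        quad = ("O4'", "C1'", "N1", "C2")
    atoms = [ligand.get(n) for n in quad]
    missing = [n for n, a in zip(quad, atoms) if a is None]
    if missing:
        raise DataError(f"glycosidic atoms missing: {missing}")
    chi = dihedral(*(a.coord for a in atoms))
    cls = "anti" if (90.0 <= chi <= 180.0 or -180.0 < chi < -90.0) else "syn"
    return ChiResult(chi=chi, cls=cls)


def _ring_coords(ligand: NucleotideLigand) -> np.ndarray:
    base = ligand.base
    if base is None:
        raise InputError(f"{ligand.comp_id}: nucleobase not recognized")
    ring = nom.PURINE_RING if ligand.is_purine else nom.PYRIMIDINE_RING
    coords = [a.coord for n in ring if (a := ligand.get(n)) is not None]
    if len(coords) < 3:
        raise DataError("fewer than 3 base ring atoms present")
    return np.array(coords)


def base_plane_angle(lig_a: NucleotideLigand, lig_b: NucleotideLigand) -> float:
    """Angle between the nucleobase least-squares planes, folded into [0, 90]."""
    n1 = plane_normal(_ring_coords(lig_a))
    n2 = plane_normal(_ring_coords(lig_b))
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


# --- classification ---------------------------------------------------------

def classify_binding_mode(complex_like, references: CanonicalReference,
                          rmsd_threshold: float = 1.5,
                          tail_rmsd_threshold: float = 2.0,
                          coord_min: float = 2.0, coord_max: float = 3.0,
                          shell_cutoff: float = 3.2,
                          hbond_dmax: float = 3.5, hbond_angmin: float = 120.0,
                          clash_factor: float = 0.6,
                          dxg_override: tuple[int, int] | None = None
                          ) -> ValidationReport:
    """Full productive-binding checklist plus binding-mode call.

    The complex must already be superposed onto the matching reference's
    protein frame.  Canonical: all-common-atom RMSD against the
    phosphate-count-matched reference within ``rmsd_threshold`` AND
    bidentate cofactor coordination.  Alternative: the phosphate/ribose
    moiety still fits (subset RMSD within ``tail_rmsd_threshold``, a more
    permissive bound than the canonical one - the known alternative-mode
    complex aligns its tail near 1.6 A) while the nucleobase plane is
    rotated by more than 45 degrees.  Anything else is reported
    nonproductive.
    """
    structure, substrate, cofactor, waters = _components(complex_like)
    reference = references.for_substrate(substrate)
    warnings: list[str] = list(waters.warnings)

    rmsd_all = substrate_rmsd(substrate, reference,
                              map_common_atoms(substrate, reference, "all_common"))
    rmsd_tail = substrate_rmsd(substrate, reference,
                               map_common_atoms(substrate, reference,
                                                "phosphate_ribose"))
    try:
        angle = base_plane_angle(substrate, reference)
    except (DataError, InputError, GeometryError) as exc:
        angle = None
        warnings.append(f"base-plane angle unavailable: {exc}")

    bidentate = None
    dxg = None
    shell_count = 0
    if cofactor is not None:
        bidentate = check_bidentate(complex_like, coord_min, coord_max)
        shell_count, _ = hydration_shell_count(structure, cofactor, shell_cutoff)
        try:
            motifs = find_dxg_motifs(structure, cofactor, override=dxg_override)
            dxg = dxg_distances(structure, motifs, cofactor)
        except (AnnotationError, DataError) as exc:
            warnings.append(f"DXG annotation failed: {exc}")
    else:
        warnings.append("no cofactor: bidentate/DXG/shell checks skipped")

    try:
        pucker = ribose_pucker(substrate)
    except DataError as exc:
        pucker = None
        warnings.append(str(exc))
    try:
        chi = glycosidic_chi(substrate)
    except DataError as exc:
        chi = None
        warnings.append(str(exc))

    hbonds = detect_hbonds(complex_like, hbond_dmax, hbond_angmin)
    clashes = steric_clashes(complex_like, clash_factor)

    is_bidentate = bidentate.bidentate if bidentate is not None else False
    if rmsd_all <= rmsd_threshold and is_bidentate:
        mode = "canonical"
    elif rmsd_tail <= tail_rmsd_threshold and angle is not None and angle > 45.0:
        mode = "alternative"
    else:
        mode = "nonproductive"

    return ValidationReport(
        substrate_rmsd_vs_reference=rmsd_all,
        phosphate_ribose_rmsd=rmsd_tail,
        bidentate=bidentate,
        dxg_distances=dxg,
        shell_water_count=shell_count,
        catalytic_water_present=waters.catalytic is not None,
        terminal_water_present=waters.terminal is not None,
        hbonds=hbonds,
        clashes=clashes,
        pucker=pucker,
        chi=chi,
        base_plane_angle_vs_reference=angle,
        mode=mode,
        warnings=warnings,
    )


# --- closed-state verification ----------------------------------------------

def validate_closed_state(model: Structure, template: Structure,
                          margin: float = 2.0,
                          template_cofactor: Atom | None = None,
                          dxg_override: tuple[int, int] | None = None
                          ) -> ClosedStateReport:
    """Check that a model adopts the closed, binding-competent conformation.

    The interdomain butterfly motion of these enzymes drastically moves
    ACR1 relative to ACR4; the C-gamma distance between the two DXG
    aspartates is therefore used as a closure proxy.  The model is flagged
    open-like when its Asp-Asp distance exceeds the template's by more than
    ``margin`` (A).
    """
    if template_cofactor is None:
        metals = [res.atoms[0] for _, res in template.residues() if res.is_metal]
        if not metals:
            raise InputError("template has no metal cofactor; pass template_cofactor "
                             "or dxg_override")
        template_cofactor = metals[0]
    motifs = find_dxg_motifs(template, template_cofactor, override=dxg_override)
    asp1, asp2 = motifs.dxg_asp
    t_dd = float(np.linalg.norm(asp1.get("CG").coord - asp2.get("CG").coord))

    sup = superpose_structures(model, template)
    # locate the corresponding aspartates in the model by pairing
    from .structures import polymer_residues
    from .superpose import align_sequences
    pairing = align_sequences(polymer_residues(model), polymer_residues(template))
    model_asp = {}
    for res_m, res_t in pairing.pairs:
        if res_t is asp1 or res_t.seq_id == asp1.seq_id and res_t.comp_id == "ASP":
            model_asp.setdefault(1, res_m)
        if res_t is asp2 or res_t.seq_id == asp2.seq_id and res_t.comp_id == "ASP":
            model_asp.setdefault(2, res_m)
    if 1 not in model_asp or 2 not in model_asp:
        raise AnnotationError("could not map the template DXG aspartates onto the model")
    cg1, cg2 = model_asp[1].get("CG"), model_asp[2].get("CG")
    if cg1 is None or cg2 is None:
        raise DataError("model DXG aspartate lacks a CG atom")
    m_dd = float(np.linalg.norm(cg1.coord - cg2.coord))
    return ClosedStateReport(
        ca_rmsd=sup.rmsd,
        asp_asp_distance=m_dd,
        template_asp_asp_distance=t_dd,
        margin=margin,
        closed=m_dd <= t_dd + margin,
    )
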