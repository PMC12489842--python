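"""Synthetic test structures with planted ground truth.

Everything the validation pipeline measures can be generated here from
first principles, fully offline and bit-reproducibly:

* idealized nucleotides built from standard bond lengths/angles, with the
  ribose pucker dialed to a requested pseudorotation phase and the
  glycosidic torsion dialed to a requested chi;
* toy enzyme-site complexes - a pair of short helical segments carrying
  planted Asp-x-Gly motifs whose aspartate C-gamma atoms sit at exact
  planned distances from a placed Ca(2+), a nucleotide coordinating the
  ion through two phosphate oxygens of distinct groups at a planned
  distance, four first-shell waters and the two catalytic-region waters;
* seeded rigid + Gaussian perturbations for superposition-recovery tests.

These are geometric test vectors, not folded proteins: local geometry is
right (bond lengths, ring pucker, planarity, planted distances) but
nothing global is energetically meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nomenclature as nom
from .errors import ConstructionError, InputError
from .geometry import place_atom, plane_normal, rotation_about_axis
from .ligands import NucleotideLigand
from .structures import Atom, Residue, Structure
from .superpose import RigidTransform, kabsch_fit

__all__ = [
    "FixtureSpec",
    "make_ideal_nucleotide",
    "make_toy_complex",
    "perturb_structure",
    "rotate_base",
    "ground_truth",
]

_KINDS = ("ATP", "ADP", "GTP", "GDP", "UTP", "UDP")

#: analog component code used for each substrate kind
_ANALOG_CODE = {"ATP": "ANP", "GTP": "GNP", "UTP": "UNP", "ADP": "APN"}


@dataclass
class FixtureSpec:
    """Deterministic plan for a toy productive-site complex."""

    seed: int = 0
    kind: str = "ATP"
    pucker_P: float = 162.0        # C2'-endo, as seen in the rat-enzyme crystals
    chi: float = -120.0            # anti
    coord_distance: float = 2.4    # phosphate O - Ca, inside the 2.0-3.0 window
    shell_distance: float = 2.4    # first-shell water O - Ca
    dxg_distances: tuple[float, float] = (4.80, 4.84)
    noise_sigma: float = 0.0
    analog: bool = True


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise InputError(f"cannot infer element of atom name {name!r}")


# --- ribose ring at a target pseudorotation phase ---------------------------

_RING_ORDER = ["C1'", "C2'", "C3'", "C4'", "O4'"]


def _ring_from_phase(phase_deg: float, q: float = 0.27) -> dict[str, np.ndarray]:
    """Puckered furanose: planar pentagon + cosine out-of-plane displacements."""
    radius = 1.52 / (2.0 * math.sin(math.radians(36.0)))
    coords = {}
    for j, name in enumerate(_RING_ORDER):
        theta = math.radians(90.0 + 72.0 * j)
        z = q * math.cos(math.radians(phase_deg) + 4.0 * math.pi * j / 5.0)
        coords[name] = np.array([radius * math.cos(theta),
                                 radius * math.sin(theta), z])
    return coords


def _measure_phase(coords: dict[str, np.ndarray]) -> float:
    from .validate import pseudorotation_from_torsions
    from .geometry import dihedral
    quads = [("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
             ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
             ("C3'", "C4'", "O4'", "C1'")]
    nu = [dihedral(*(coords[n] for n in quad)) for quad in quads]
    return pseudorotation_from_torsions(nu)[0]


def _ring_at_pucker(target_P: float, q: float = 0.27) -> dict[str, np.ndarray]:
    """Solve the displacement phase so the measured phase hits ``target_P``."""
    def wrap(x: float) -> float:
        return (x + 180.0) % 360.0 - 180.0

    best_phi, best_err = 0.0, 1e9
    for step, center, span in ((2.0, 180.0, 180.0), (0.05, None, 2.0),
                               (0.001, None, 0.05)):
        lo = (best_phi - span) if center is None else (center - span)
        hi = (best_phi + span) if center is None else (center + span)
        phi = lo
        while phi <= hi:
            err = abs(wrap(_measure_phase(_ring_from_phase(phi, q)) - target_P))
            if err < best_err:
                best_phi, best_err = phi, err
            phi += step
    if best_err > 0.5:
        raise ConstructionError(
            f"could not realize pseudorotation phase {target_P} deg "
            f"(residual {best_err:.2f} deg)")
    return _ring_from_phase(best_phi, q)


# --- full nucleotide ---------------------------------------------------------

def make_ideal_nucleotide(kind: str, P: float = 162.0, chi: float = -120.0,
                          analog: bool = False) -> NucleotideLigand:
    """Idealized nucleotide with the requested pucker phase and chi.

    Built from standard bond lengths and angles with an extended
    (linear-like) phosphate tail.  ``analog=True`` produces the
    non-hydrolyzable imido form (bridging N3B for triphosphates, N3A for
    the ADP analog).
    """
    kind = kind.upper()
    if kind not in _KINDS:
        raise InputError(f"unknown nucleotide kind {kind!r}; expected one of {_KINDS}")
    if not 0.0 <= P % 360.0 < 360.0 or not -180.0 < chi <= 180.0:
        raise InputError("P must be a finite angle and chi in (-180, 180]")
    if analog and kind not in _ANALOG_CODE:
        raise InputError(f"no imido-analog component defined for {kind}")

    base = kind[0]
    n_phos = 3 if kind.endswith("TP") else 2
    pos = _ring_at_pucker(P)

    def put(name, a, b, c, bond, ang, tor):
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, ang, tor)

    # exocyclic sugar substituents
    put("O2'", "O4'", "C1'", "C2'", 1.41, 109.5, -121.0)
    put("O3'", "C1'", "C2'", "C3'", 1.42, 110.0, 121.0)
    put("C5'", "C2'", "C3'", "C4'", 1.51, 115.0, -122.0)
    put("O5'", "C3'", "C4'", "C5'", 1.44, 110.0, 180.0)

    # glycosidic nitrogen on the same face as C5' (beta anomer)
    gly_n = nom.GLYCOSIDIC_N[base]
    candidates = []
    for tor in (121.0, -121.0):
        candidates.append(place_atom(pos["C4'"], pos["O4'"], pos["C1'"],
                                     1.47, 108.0, tor))
    ring_pts = np.array([pos[n] for n in nom.RIBOSE_RING])
    normal = plane_normal(ring_pts)
    center = ring_pts.mean(axis=0)
    side_c5 = np.sign(np.dot(pos["C5'"] - center, normal))
    pos[gly_n] = max(candidates,
                     key=lambda p: side_c5 * np.dot(p - center, normal))

    # phosphate tail, extended
    put("PA", "C4'", "C5'", "O5'", 1.60, 120.0, 180.0)
    bridge_a = "N3A" if (analog and n_phos == 2) else "O3A"
    put(bridge_a, "C5'", "O5'", "PA", 1.60, 104.0, 180.0)
    put("O1A", "C5'", "O5'", "PA", 1.48, 109.0, 60.0)
    put("O2A", "C5'", "O5'", "PA", 1.48, 109.0, -60.0)
    put("PB", "O5'", "PA", bridge_a, 1.60, 120.0, 180.0)
    if n_phos == 3:
        bridge_b = "N3B" if analog else "O3B"
        put(bridge_b, "PA", bridge_a, "PB", 1.60, 104.0, 180.0)
        put("O1B", "PA", bridge_a, "PB", 1.48, 109.0, 60.0)
        put("O2B", "PA", bridge_a, "PB", 1.48, 109.0, -60.0)
        put("PG", bridge_a, "PB", bridge_b, 1.60, 120.0, 180.0)
        put("O3G", "PB", bridge_b, "PG", 1.52, 104.0, 180.0)
        put("O1G", "PB", bridge_b, "PG", 1.52, 109.0, 60.0)
        put("O2G", "PB", bridge_b, "PG", 1.52, 109.0, -60.0)
    else:
        put("O3B", "PA", bridge_a, "PB", 1.52, 104.0, 180.0)
        put("O1B", "PA", bridge_a, "PB", 1.52, 109.0, 60.0)
        put("O2B", "PA", bridge_a, "PB", 1.52, 109.0, -60.0)

    # nucleobase, planar
    if base in ("A", "G"):
        put("C4", "O4'", "C1'", "N9", 1.37, 127.0, chi)
        put("C8", "O4'", "C1'", "N9", 1.37, 127.0, chi + 180.0)
        put("N7", "C4", "N9", "C8", 1.31, 113.0, 0.0)
        put("C5", "C8", "N9", "C4", 1.38, 106.0, 0.0)
        put("C6", "N9", "C4", "C5", 1.41, 132.0, 180.0)
        put("N1", "C4", "C5", "C6", 1.35, 117.0, 0.0)
        put("C2", "C5", "C6", "N1", 1.34, 118.0, 0.0)
        put("N3", "C6", "N1", "C2", 1.33, 129.0, 0.0)
        if base == "A":
            put("N6", "C4", "C5", "C6", 1.34, 120.0, 180.0)
        else:
            put("O6", "C4", "C5", "C6", 1.23, 120.0, 180.0)
            put("N2", "C6", "N1", "C2", 1.34, 120.0, 180.0)
    else:  # uracil
        put("C2", "O4'", "C1'", "N1", 1.38, 121.0, chi)
        put("C6", "O4'", "C1'", "N1", 1.38, 121.0, chi + 180.0)
        put("N3", "C6", "N1", "C2", 1.37, 115.0, 0.0)
        put("C4", "N1", "C2", "N3", 1.38, 127.0, 0.0)
        put("C5", "C2", "N3", "C4", 1.44, 115.0, 0.0)
        put("O2", "C6", "N1", "C2", 1.22, 123.0, 180.0)
        put("O4", "C2", "N3", "C4", 1.23, 120.0, 180.0)

    comp_id = _ANALOG_CODE[kind] if analog else kind
    order = (nom.NUCLEOTIDE_ATOMS[kind] if not analog else
             [nom.OXYGEN_TO_BRIDGE[n] if
              (n == "O3B" and n_phos == 3) or (n == "O3A" and n_phos == 2)
              else n for n in nom.NUCLEOTIDE_ATOMS[kind]])
    atoms = []
    for i, name in enumerate(order):
        atoms.append(Atom(name=name, element=_element_of(name),
                          coord=pos[name], serial=i + 1))
    bridge = None
    if analog:
        bridge = "N3B" if n_phos == 3 else "N3A"
    return NucleotideLigand(comp_id=comp_id, atoms=atoms, analog_bridge=bridge)


# --- base rotation (alternative binding mode emulation) ----------------------

def rotate_base(ligand: NucleotideLigand, angle_deg: float) -> NucleotideLigand:
    """Rotate the nucleobase about an in-plane axis through the glycosidic N.

    Tilts the base plane by ``angle_deg`` while leaving phosphates and
    ribose untouched - the geometry of the alternative binding mode in
    which the tail still aligns but the base is swung away.
    """
    out = ligand.copy()
    base = out.base
    if base is None:
        raise InputError("ligand has no recognizable base")
    ring = nom.PURINE_RING if out.is_purine else nom.PYRIMIDINE_RING
    ring_pts = out.coords(ring)
    normal = plane_normal(ring_pts)
    pivot = out.get(out.glycosidic_nitrogen).coord.copy()
    inplane = ring_pts.mean(axis=0) - pivot
    inplane -= np.dot(inplane, normal) * normal
    rot = rotation_about_axis(inplane, angle_deg)
    for name in nom.BASE_ATOMS[base]:
        atom = out.get(name)
        if atom is not None:
            atom.coord = pivot + rot @ (atom.coord - pivot)
    return out


# --- toy complex -------------------------------------------------------------

_HELIX_SEQ = ["ALA", "ALA", "ALA", "ASP", "ALA", "GLY", "ALA", "ALA", "ALA",
              "ALA", "ALA"]


def _helix_residues(center: np.ndarray, axis: np.ndarray, ref: np.ndarray,
                    start_seq: int) -> list[Residue]:
    """A short ideal helix (CA trace + schematic N/C/O backbone)."""
    axis = axis / np.linalg.norm(axis)
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    n = len(_HELIX_SEQ)
    cas = []
    for i in range(n):
        theta = math.radians(100.0 * i)
        cas.append(center + 2.3 * (math.cos(theta) * e1 + math.sin(theta) * e2)
                   + (i - (n - 1) / 2.0) * 1.5 * axis)
    residues = []
    for i, comp in enumerate(_HELIX_SEQ):
        ca = cas[i]
        prev_ca = cas[i - 1] if i > 0 else ca - 3.8 * axis
        next_ca = cas[i + 1] if i < n - 1 else ca + 3.8 * axis
        t_in = ca - prev_ca
        t_in /= np.linalg.norm(t_in)
        t_out = next_ca - ca
        t_out /= np.linalg.norm(t_out)
        atoms = [
            Atom("N", "N", ca - 1.2 * t_in),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 1.2 * t_out),
            Atom("O", "O", ca + 1.2 * t_out + 1.23 * np.cross(t_out, e2
                  if abs(np.dot(t_out, e2)) < 0.9 else e1)),
        ]
        residues.append(Residue(comp, start_seq + i, "", atoms))
    return residues


def _plant_aspartate(residues: list[Residue], toward: np.ndarray,
                     cg_distance: float) -> None:
    """Point the planted Asp side chain at ``toward`` with CG at an exact range."""
    asp = next(r for r in residues if r.comp_id == "ASP")
    ca = asp.get("CA").coord
    direction = ca - toward
    direction /= np.linalg.norm(direction)
    cg = toward + cg_distance * direction
    cb = cg + 1.53 * direction
    perp = np.cross(direction, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    od1 = cg - 1.25 * (0.5 * direction - 0.866 * perp)
    od2 = cg - 1.25 * (0.5 * direction + 0.866 * perp)
    asp.atoms.extend([Atom("CB", "C", cb), Atom("CG", "C", cg),
                      Atom("OD1", "O", od1), Atom("OD2", "O", od2)])


def _coordination_targets(ligand: NucleotideLigand, d: float
                          ) -> tuple[list[str], np.ndarray]:
    """Pick two terminal oxygens of distinct phosphate groups and target
    positions placing both exactly ``d`` from the origin."""
    if ligand.get("PG") is not None:
        groups = (["O1B", "O2B"], ["O1G", "O2G"])
        anchor_p = "PG"
    else:
        groups = (["O1A", "O2A"], ["O1B", "O2B"])
        anchor_p = "PB"
    best = None
    for na in groups[0]:
        for nb in groups[1]:
            a, b = ligand.get(na), ligand.get(nb)
            if a is None or b is None:
                continue
            s = float(np.linalg.norm(a.coord - b.coord))
            if best is None or s < best[0]:
                best = (s, na, nb)
    if best is None:
        raise ConstructionError("ligand lacks terminal phosphate oxygens")
    s, na, nb = best
    if s >= 2.0 * d * 0.98:
        raise ConstructionError(
            f"coordinating oxygens are {s:.2f} A apart; cannot both sit at "
            f"{d:.2f} A from the cofactor (triangle violation)")
    y0 = math.sqrt(d * d - (s / 2.0) ** 2)
    o1_t = np.array([s / 2.0, y0, 0.0])
    o2_t = np.array([-s / 2.0, y0, 0.0])
    p = ligand.get(anchor_p).coord
    r1 = float(np.linalg.norm(p - ligand.get(na).coord))
    r2 = float(np.linalg.norm(p - ligand.get(nb).coord))
    x = (r2 * r2 - r1 * r1) / (2.0 * s)
    arg = r1 * r1 - (x - s / 2.0) ** 2
    if arg <= 0:
        raise ConstructionError("phosphate anchor cannot close the coordination triangle")
    p_t = np.array([x, y0 + math.sqrt(arg), 0.0])
    targets = np.array([o1_t, o2_t, p_t])
    return [na, nb, anchor_p], targets


_SHELL_DIRECTIONS = np.array([
    [0.0, 0.0, 1.0],
    [0.0, 0.0, -1.0],
    [1.0, -1.0, 1.0],
    [-1.0, -1.0, -1.0],
])


def make_toy_complex(spec: FixtureSpec) -> Structure:
    """Build a self-contained productive-site complex from a distance plan.

    Chains: A = scaffold protein with two planted DXG motifs, L = the
    nucleotide (analog by default), M = the Ca(2+) cofactor at the origin,
    W = the six conserved waters.  All planned distances are honored to
    numerical precision; seeded Gaussian noise (``noise_sigma``) is applied
    last, so the noiseless construction is the ground truth.
    """
    ligand = make_ideal_nucleotide(spec.kind, spec.pucker_P, spec.chi,
                                   analog=spec.analog)
    anchor_names, targets = _coordination_targets(ligand, spec.coord_distance)
    transform, fit_rmsd = kabsch_fit(ligand.coords(anchor_names), targets)
    if fit_rmsd > 1e-6:
        raise ConstructionError(
            f"coordination placement is not congruent (residual {fit_rmsd:.2e} A)")
    ligand = ligand.transformed(transform)
    ligand.chain, ligand.seq_id = "L", 1

    cofactor = Atom("CA", "CA", np.zeros(3))

    # first hydration shell + the two catalytic-region waters
    waters = []
    for direction in _SHELL_DIRECTIONS:
        u = direction / np.linalg.norm(direction)
        waters.append(spec.shell_distance * u)
    term_p = ligand.get("PG") or ligand.get("PB")
    bridge = (ligand.get("N3B") or ligand.get("O3B")) if spec.kind.endswith("TP") \
        else (ligand.get("N3A") or ligand.get("O3A"))
    axis_out = term_p.coord - bridge.coord
    axis_out /= np.linalg.norm(axis_out)
    catalytic = term_p.coord + 3.3 * axis_out
    group = "G" if ligand.get("PG") is not None else "B"
    o_term = ligand.get(f"O3{group}") or ligand.get(f"O1{group}")
    out_dir = o_term.coord - term_p.coord
    out_dir /= np.linalg.norm(out_dir)
    terminal = o_term.coord + 2.8 * out_dir
    for name, w in (("catalytic", catalytic), ("terminal", terminal)):
        if np.linalg.norm(w) <= 3.2:
            raise ConstructionError(
                f"planned {name} water falls inside the cofactor first shell")
    waters += [catalytic, terminal]

    # scaffold helices carrying the DXG motifs
    d1, d2 = spec.dxg_distances
    dir1 = np.array([-1.0, -1.0, 0.0]) / math.sqrt(2.0)
    dir2 = np.array([1.0, -1.0, 0.0]) / math.sqrt(2.0)
    helix1 = _helix_residues(11.0 * dir1, np.array([0.0, 0.0, 1.0]), -dir1, 1)
    helix2 = _helix_residues(11.0 * dir2, np.array([0.0, 0.0, 1.0]), -dir2, 21)
    _plant_aspartate(helix1, np.zeros(3), d1)
    _plant_aspartate(helix2, np.zeros(3), d2)

    chains = {
        "A": helix1 + helix2,
        "L": [ligand.to_residue()],
        "M": [Residue("CA", 1, "", [cofactor])],
        "W": [Residue("HOH", i + 1, "", [Atom("O", "O", w)])
              for i, w in enumerate(waters)],
    }
    structure = Structure(id=f"toy-{spec.kind.lower()}", chains=chains)
    serial = 0
    for atom in structure.atoms():
        serial += 1
        atom.serial = serial
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for atom in structure.atoms():
            atom.coord = atom.coord + rng.normal(0.0, spec.noise_sigma, 3)
    return structure


def ground_truth(spec: FixtureSpec) -> dict:
    """The planted quantities of :func:`make_toy_complex`, for reports."""
    return {
        "kind": spec.kind,
        "analog": spec.analog,
        "pucker_P": spec.pucker_P,
        "chi": spec.chi,
        "coord_distance": spec.coord_distance,
        "shell_distance": spec.shell_distance,
        "shell_count": 4,
        "dxg_distances": list(spec.dxg_distances),
        "n_waters": 6,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }


# --- perturbation -------------------------------------------------------------

def perturb_structure(structure: Structure, rotation_angle: float = 0.0,
                      axis=(0.0, 0.0, 1.0), translation=(0.0, 0.0, 0.0),
                      noise_sigma: float = 0.0, seed: int = 0) -> Structure:
    """Rigidly move a structure (rotation about the origin, then translation)
    and optionally add seeded isotropic Gaussian coordinate noise.

    Noise is applied after the rigid motion, so the planted transform stays
    the ground truth for superposition-recovery tests.
    """
    rot = rotation_about_axis(np.asarray(axis, dtype=float), rotation_angle) \
        if rotation_angle else np.eye(3)
    transform = RigidTransform(rot, np.asarray(translation, dtype=float))
    out = structure.copy()
    rng = np.random.default_rng(seed)
    for atom in out.atoms():
        atom.coord = transform.apply(atom.coord)
        if noise_sigma > 0:
            atom.coord = atom.coord + rng.normal(0.0, noise_sigma, 3)
    return out
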