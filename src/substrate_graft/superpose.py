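"""Protein superposition and in-frame substrate RMSD.

The measurement convention throughout: two complexes are first brought into
a common frame by a sequence-guided, least-squares rigid superposition of
their protein C-alpha traces with iterative outlier rejection (the behavior
of the classic *align* tools).  The substrate RMSD is then a plain
coordinate RMSD over an explicit atom correspondence, with **no refitting**
of the ligands themselves - it measures how far the bound nucleotide sits
from the reference nucleotide inside the protein-aligned frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TYPE_CHECKING

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import nomenclature as nom
from .errors import (
    ConvergenceError,
    DataError,
    GeometryError,
    InputError,
    MappingError,
)
from .structures import Residue, Structure

if TYPE_CHECKING:  # pragma: no cover
    from .ligands import NucleotideLigand

__all__ = [
    "ResiduePairing",
    "RigidTransform",
    "SuperpositionResult",
    "AtomMap",
    "align_sequences",
    "kabsch_fit",
    "iterative_superpose",
    "apply_transform",
    "map_common_atoms",
    "substrate_rmsd",
    "superpose_structures",
]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        if np.max(np.abs(self.rotation.T @ self.rotation - np.eye(3))) > 1e-8:
            raise ValueError("rotation matrix is not orthogonal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.reshape(-1).tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "RigidTransform":
        return cls(np.array(payload["rotation"], dtype=float).reshape(3, 3),
                   np.array(payload["translation"], dtype=float))


@dataclass
class ResiduePairing:
    pairs: list[tuple[Residue, Residue]]
    identity: float
    aligned_length: int


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    cycles_run: int
    retained_pairs: int
    rejected_pairs: int
    rmsd_per_cycle: list[float] = field(default_factory=list)


@dataclass
class AtomMap:
    pairs: list[tuple[str, str]]
    subset_tag: str


# --- sequence pairing -------------------------------------------------------

def _one_letter(residues: Sequence[Residue]) -> str:
    return "".join(nom.AA_THREE_TO_ONE.get(r.comp_id, "X") for r in residues)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def align_sequences(chain_a: Sequence[Residue], chain_b: Sequence[Residue]) -> ResiduePairing:
    """Global sequence alignment of two residue chains (BLOSUM62, 10/0.5).

    Only polymer residues that carry a C-alpha atom participate.  Gap
    columns produce no pair; identity is the fraction of identical letters
    over aligned (paired) columns.
    """
    res_a = [r for r in chain_a if r.is_polymer and "CA" in r]
    res_b = [r for r in chain_b if r.is_polymer and "CA" in r]
    if len(res_a) < 2 or len(res_b) < 2:
        raise InputError("sequence alignment needs >= 2 polymer residues with "
                         "C-alpha atoms on each side")
    seq_a, seq_b = _one_letter(res_a), _one_letter(res_b)
    alignment = _make_aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[Residue, Residue]] = []
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            pairs.append((res_a[i], res_b[j]))
            if seq_a[i] == seq_b[j]:
                matches += 1
    if not pairs:
        raise InputError("alignment produced no paired columns")
    return ResiduePairing(pairs=pairs,
                          identity=matches / len(pairs),
                          aligned_length=len(pairs))


# --- rigid fitting ----------------------------------------------------------

def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid fit of ``coords_a`` onto ``coords_b``.

    Returns the transform minimizing the RMSD of the transformed A against
    B, with reflections excluded, plus that minimal RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise GeometryError(f"rigid fitting needs >= 3 points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sing_a = np.linalg.svd(a0, compute_uv=False)
    if sing_a[1] < 1e-8:
        raise GeometryError("degenerate (collinear) point set: rotation is not unique")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, cb - rot @ ca)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(a) - b) ** 2, axis=1))))
    return transform, rmsd


def _ca_coords(pairs: list[tuple[Residue, Residue]]) -> tuple[np.ndarray, np.ndarray]:
    a, b = [], []
    for res_a, res_b in pairs:
        atom_a, atom_b = res_a.get("CA"), res_b.get("CA")
        if atom_a is None or atom_b is None:
            continue
        a.append(atom_a.coord)
        b.append(atom_b.coord)
    return np.array(a), np.array(b)


def iterative_superpose(struct_a: Structure, struct_b: Structure,
                        pairing: ResiduePairing, cycles: int = 5,
                        reject_cutoff: float = 2.0) -> SuperpositionResult:
    """Superpose A onto B with iterative rejection of deviant residue pairs.

    Cycle 0 fits all paired C-alpha atoms; each further cycle drops pairs
    deviating by more than ``reject_cutoff`` and refits, stopping early when
    nothing is dropped.  The reported RMSD covers the retained pairs only.
    """
    if not pairing.pairs:
        raise InputError("empty residue pairing")
    if cycles < 0 or reject_cutoff <= 0:
        raise InputError("cycles must be >= 0 and reject_cutoff > 0")
    a_all, b_all = _ca_coords(pairing.pairs)
    total = a_all.shape[0]
    if total < 3:
        raise InputError("fewer than 3 paired C-alpha atoms")
    keep = np.ones(total, dtype=bool)
    transform, rmsd = kabsch_fit(a_all, b_all)
    history = [rmsd]
    cycles_run = 0
    for _ in range(cycles):
        dev = np.linalg.norm(transform.apply(a_all) - b_all, axis=1)
        drop = keep & (dev > reject_cutoff)
        if not drop.any():
            break
        keep &= ~drop
        cycles_run += 1
        if keep.sum() < 3:
            raise ConvergenceError(
                f"outlier rejection left {int(keep.sum())} pairs (< 3); "
                f"last retained count {int(keep.sum() + drop.sum())}")
        transform, rmsd = kabsch_fit(a_all[keep], b_all[keep])
        history.append(rmsd)
    return SuperpositionResult(
        transform=transform,
        rmsd=rmsd,
        cycles_run=cycles_run,
        retained_pairs=int(keep.sum()),
        rejected_pairs=int(total - keep.sum()),
        rmsd_per_cycle=history,
    )


def superpose_structures(mobile: Structure, target: Structure,
                         chain_mobile: str | None = None,
                         chain_target: str | None = None,
                         cycles: int = 5,
                         reject_cutoff: float = 2.0) -> SuperpositionResult:
    """Sequence-align + iteratively superpose two protein structures."""
    from .structures import polymer_residues

    res_a = polymer_residues(mobile, chain_mobile)
    res_b = polymer_residues(target, chain_target)
    pairing = align_sequences(res_a, res_b)
    return iterative_superpose(mobile, target, pairing, cycles, reject_cutoff)


def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    """Return a copy of the structure with every coordinate mapped x -> Rx+t."""
    out = structure.copy()
    for atom in out.atoms():
        atom.coord = transform.apply(atom.coord)
    return out


# --- ligand atom correspondence --------------------------------------------

_SUBSETS = ("all_common", "phosphate_ribose", "nucleobase")


def _tail_names(names: set[str]) -> set[str]:
    tail = set(nom.PHOSPHATE_TRI) | set(nom.RIBOSE_ATOMS) | {"N3A", "N3B"}
    return names & tail


def _base_names(ligand: "NucleotideLigand") -> set[str]:
    base = nom.base_letter(ligand.comp_id, ligand.atom_names())
    if base is None:
        return set()
    return set(ligand.atom_names()) & set(nom.BASE_ATOMS[base])


def map_common_atoms(lig_a: "NucleotideLigand", lig_b: "NucleotideLigand",
                     subset: str = "all_common") -> AtomMap:
    """Deterministic atom-name correspondence between two nucleotides.

    ``all_common`` pairs the shared phosphate-tail and ribose atoms plus the
    shared base atoms when both bases are of the same class (purine/purine
    or pyrimidine/pyrimidine; across classes the base names collide without
    being chemically equivalent, so the base contributes nothing).
    ``phosphate_ribose`` restricts to tail + ribose; ``nucleobase`` to ring
    atoms.  The imido bridge of an analog is treated as equivalent to the
    bridging oxygen it replaces (N3B ~ O3B, N3A ~ O3A).
    """
    if subset not in _SUBSETS:
        raise InputError(f"unknown subset {subset!r}; expected one of {_SUBSETS}")
    names_a = set(lig_a.atom_names())
    names_b = set(lig_b.atom_names())

    def canonical(names: set[str]) -> dict[str, str]:
        # map canonical (oxygen) name -> actual name, folding analog bridges
        out = {}
        for n in names:
            out[nom.BRIDGE_TO_OXYGEN.get(n, n)] = n
        return out

    pairs: list[tuple[str, str]] = []
    if subset in ("all_common", "phosphate_ribose"):
        can_a = canonical(_tail_names(names_a))
        can_b = canonical(_tail_names(names_b))
        order = nom.PHOSPHATE_TRI + nom.RIBOSE_ATOMS
        for name in order:
            if name in can_a and name in can_b:
                pairs.append((can_a[name], can_b[name]))
    if subset in ("all_common", "nucleobase"):
        base_a = nom.base_letter(lig_a.comp_id, names_a)
        base_b = nom.base_letter(lig_b.comp_id, names_b)
        purines = {"A", "G"}
        same_class = (base_a in purines) == (base_b in purines)
        if base_a and base_b and same_class:
            if subset == "nucleobase":
                candidates = nom.PURINE_RING if base_a in purines else nom.PYRIMIDINE_RING
            else:
                candidates = nom.BASE_ATOMS[base_a]
            shared = _base_names(lig_a) & _base_names(lig_b)
            for name in candidates:
                if name in shared:
                    pairs.append((name, name))
        elif subset == "nucleobase":
            raise MappingError(
                f"no base correspondence between {lig_a.comp_id} and {lig_b.comp_id} "
                "(different base classes)")
    if not pairs:
        raise MappingError(
            f"no common atoms between {lig_a.comp_id} and {lig_b.comp_id} "
            f"for subset {subset!r}")
    return AtomMap(pairs=pairs, subset_tag=subset)


def substrate_rmsd(lig_a: "NucleotideLigand", lig_b: "NucleotideLigand",
                   atom_map: AtomMap) -> float:
    """Plain coordinate RMSD over mapped atoms - no refitting.

    Both ligands must already sit in a common frame (their proteins having
    been superposed); the value measures the ligand displacement inside
    that frame.
    """
    if not atom_map.pairs:
        raise InputError("empty atom map")
    a, b = [], []
    for name_a, name_b in atom_map.pairs:
        atom_a, atom_b = lig_a.get(name_a), lig_b.get(name_b)
        if atom_a is None or atom_b is None:
            raise DataError(f"mapped atom missing: {name_a!r}/{name_b!r}")
        a.append(atom_a.coord)
        b.append(atom_b.coord)
    diff = np.array(a) - np.array(b)
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
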