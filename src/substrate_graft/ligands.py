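"""Small-molecule operations: extraction, analog conversion, hybrid
assembly and transplantation.

The modeling protocol implemented here builds enzyme-substrate complexes
by copying crystallographic content rather than re-docking it: the bound
nucleotide (a non-hydrolyzable imido analog), the divalent metal cofactor
and the conserved active-site waters are transplanted rigidly from a
solved complex into a superposed target model.  Analogs are converted to
true substrates by substituting the single bridging nitrogen back into
oxygen, keeping every coordinate bit-identical.  Diphosphate complexes
for which no crystal exists (GDP, UDP) are assembled as hybrids: the
nucleobase of the corresponding triphosphate is rigid-fitted onto the ADP
analog's base, then combined with the ADP analog's sugar and phosphate
tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import nomenclature as nom
from .errors import (
    ClassificationError,
    GeometryError,
    InputError,
    SelectionError,
)
from .structures import Atom, Residue, Selector, Structure, select_atoms
from .superpose import (
    AtomMap,
    RigidTransform,
    SuperpositionResult,
    kabsch_fit,
)

__all__ = [
    "NucleotideLigand",
    "SiteWaters",
    "GraftedComplex",
    "extract_component",
    "analog_to_substrate",
    "build_hybrid_diphosphate",
    "select_site_waters",
    "graft_complex",
    "identify_components",
]


@dataclass
class NucleotideLigand:
    """A nucleotide (or imido analog) with canonical atom nomenclature."""

    comp_id: str
    atoms: list[Atom]
    analog_bridge: str | None = None  # "N3B" or "N3A" when an analog
    seq_id: int = 1
    chain: str = "L"

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def get(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    @property
    def n_phosphates(self) -> int:
        return sum(1 for a in self.atoms if a.element.upper() == "P")

    @property
    def base(self) -> str | None:
        return nom.base_letter(self.comp_id, self.atom_names())

    @property
    def is_purine(self) -> bool:
        return self.base in ("A", "G")

    @property
    def glycosidic_nitrogen(self) -> str:
        return "N9" if self.is_purine else "N1"

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.coord for a in self.atoms])
        out = []
        for name in names:
            atom = self.get(name)
            if atom is None:
                raise InputError(f"{self.comp_id} has no atom {name!r}")
            out.append(atom.coord)
        return np.array(out)

    def copy(self) -> "NucleotideLigand":
        return NucleotideLigand(self.comp_id, [a.copy() for a in self.atoms],
                                self.analog_bridge, self.seq_id, self.chain)

    def transformed(self, transform: RigidTransform) -> "NucleotideLigand":
        out = self.copy()
        for atom in out.atoms:
            atom.coord = transform.apply(atom.coord)
        return out

    def to_residue(self) -> Residue:
        return Residue(self.comp_id, self.seq_id, "", [a.copy() for a in self.atoms])

    def _validate(self) -> None:
        suffix = self.comp_id[1:] if self.comp_id in nom.NUCLEOTIDE_ATOMS else None
        if suffix == "TP" and self.n_phosphates != 3:
            raise ClassificationError(f"{self.comp_id} must carry 3 phosphorus atoms")
        if suffix == "DP" and self.n_phosphates != 2:
            raise ClassificationError(f"{self.comp_id} must carry 2 phosphorus atoms")


@dataclass
class SiteWaters:
    """The conserved active-site waters of a productive complex.

    ``shell`` holds the cofactor's first hydration shell (four expected),
    ``catalytic`` the water positioned for in-line attack on the terminal
    phosphorus, ``terminal`` the extra water near the last phosphate group.
    """

    shell: list[Residue] = field(default_factory=list)
    catalytic: Residue | None = None
    terminal: Residue | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return (len(self.shell) == 4 and self.catalytic is not None
                and self.terminal is not None)

    def all_waters(self) -> list[Residue]:
        extra = [w for w in (self.catalytic, self.terminal) if w is not None]
        return list(self.shell) + extra

    def transformed(self, transform: RigidTransform) -> "SiteWaters":
        def tf(res: Residue | None) -> Residue | None:
            if res is None:
                return None
            out = res.copy()
            for atom in out.atoms:
                atom.coord = transform.apply(atom.coord)
            return out
        return SiteWaters(shell=[tf(w) for w in self.shell],
                          catalytic=tf(self.catalytic),
                          terminal=tf(self.terminal),
                          warnings=list(self.warnings))


@dataclass
class GraftedComplex:
    """A target protein carrying a transplanted substrate bundle."""

    target: Structure
    substrate: NucleotideLigand
    cofactor: Atom | None
    waters: SiteWaters
    provenance: dict = field(default_factory=dict)

    @property
    def protein(self) -> Structure:
        return select_atoms(self.target, Selector(category="polymer"))

    def to_structure(self) -> Structure:
        return self.target


# --- extraction -------------------------------------------------------------

def _detect_bridge(residue: Residue) -> str | None:
    for name in ("N3B", "N3A"):
        atom = residue.get(name)
        if atom is not None and atom.element.upper() == "N":
            return name
    return None


def extract_component(structure: Structure, selector: Selector) -> NucleotideLigand:
    """Pull the single nucleotide component matching ``selector``.

    The residue must carry a ribose (C1' and the furanose ring) and at
    least one phosphorus; the imido bridge of analogs is detected from the
    atom names/elements.
    """
    matches: list[tuple[str, Residue]] = []
    for chain_name, res in structure.residues():
        if selector.matches(chain_name, res) and res.category == "ligand":
            matches.append((chain_name, res))
        elif selector.matches(chain_name, res) and res.category in ("water", "metal"):
            raise ClassificationError(
                f"selector matched a {res.category} ({res.comp_id} {res.seq_id}), "
                "not a nucleotide component")
    if len(matches) != 1:
        raise SelectionError(
            f"selector resolved to {len(matches)} small-molecule residues; need exactly 1")
    chain_name, res = matches[0]
    names = {a.name for a in res.atoms}
    if not set(nom.RIBOSE_RING) <= names or not any(
            a.element.upper() == "P" for a in res.atoms):
        raise ClassificationError(
            f"{res.comp_id} {res.seq_id} is not a recognizable nucleotide scaffold")
    ligand = NucleotideLigand(
        comp_id=res.comp_id,
        atoms=[a.copy() for a in res.atoms],
        analog_bridge=_detect_bridge(res),
        seq_id=res.seq_id,
        chain=chain_name,
    )
    if ligand.base is None:
        raise ClassificationError(
            f"{res.comp_id} {res.seq_id}: nucleobase not recognized")
    return ligand


# --- analog conversion ------------------------------------------------------

def analog_to_substrate(ligand: NucleotideLigand) -> NucleotideLigand:
    """Convert an imido analog into the true substrate.

    Exactly one atom record changes: the bridging nitrogen becomes the
    bridging oxygen (N3B -> O3B or N3A -> O3A), with its coordinates - and
    every other atom's - bit-identical.  The component code becomes the
    true nucleotide.  Calling this on a non-analog is an error, never a
    silent identity.
    """
    if ligand.analog_bridge is None:
        raise InputError(
            f"{ligand.comp_id} carries no imido bridge; refusing a no-op conversion")
    bridge = ligand.analog_bridge
    out = ligand.copy()
    atom = out.get(bridge)
    if atom is None:
        raise InputError(f"declared bridge atom {bridge} not present")
    atom.name = nom.BRIDGE_TO_OXYGEN[bridge]
    atom.element = "O"
    out.analog_bridge = None
    base = ligand.base
    if base is None:
        raise ClassificationError("cannot infer nucleobase for substrate naming")
    out.comp_id = nom.substrate_code(base, ligand.n_phosphates)
    return out


# --- hybrid assembly --------------------------------------------------------

#: glycosidic-geometry-preserving pyrimidine -> purine correspondence
_PYR_TO_PUR = [("N1", "N9"), ("C2", "C4"), ("C6", "C8"), ("C1'", "C1'")]


def _base_fit_map(base_donor: NucleotideLigand,
                  tail_donor: NucleotideLigand) -> list[tuple[str, str]]:
    if base_donor.is_purine and tail_donor.is_purine:
        pairs = [(n, n) for n in nom.PURINE_RING] + [("C1'", "C1'")]
    elif not base_donor.is_purine and tail_donor.is_purine:
        pairs = list(_PYR_TO_PUR)
    elif base_donor.is_purine and not tail_donor.is_purine:
        pairs = [(b, a) for a, b in _PYR_TO_PUR]
    else:
        pairs = [(n, n) for n in nom.PYRIMIDINE_RING] + [("C1'", "C1'")]
    return pairs


def build_hybrid_diphosphate(base_donor: NucleotideLigand,
                             tail_donor: NucleotideLigand) -> NucleotideLigand:
    """Assemble a diphosphate by fragment recombination.

    The base donor (e.g. a GTP or UTP analog) is rigid-fitted onto the
    tail donor (the ADP analog) through a nucleobase atom correspondence;
    the product then takes the tail donor's sugar and phosphate-tail
    coordinates exactly and the base donor's nucleobase in the fitted
    frame.  Both fragments are therefore copied rigidly; only their
    relative placement comes from the fit.
    """
    if base_donor.base is None or tail_donor.base is None:
        raise InputError("both ligands need a recognizable nucleobase")
    fit_pairs = _base_fit_map(base_donor, tail_donor)
    for name_a, name_b in fit_pairs:
        if base_donor.get(name_a) is None or tail_donor.get(name_b) is None:
            raise InputError(f"fit atom missing: {name_a!r}/{name_b!r}")
    coords_a = base_donor.coords([p[0] for p in fit_pairs])
    coords_b = tail_donor.coords([p[1] for p in fit_pairs])
    transform, fit_rmsd = kabsch_fit(coords_a, coords_b)
    if fit_rmsd > 1.0:
        raise GeometryError(
            f"nucleobase fit RMSD {fit_rmsd:.2f} A > 1.0 A: bases too dissimilar "
            "for the stated correspondence")
    fitted_base = base_donor.transformed(transform)

    base_names = set(nom.BASE_ATOMS[base_donor.base])
    tail_base_names = set(nom.BASE_ATOMS[tail_donor.base])
    atoms: list[Atom] = []
    for atom in tail_donor.atoms:
        if atom.name in tail_base_names:
            continue  # the tail donor's own base is discarded
        atoms.append(atom.copy())
    for atom in fitted_base.atoms:
        if atom.name in base_names:
            atoms.append(atom.copy())

    out = NucleotideLigand(
        comp_id=nom.substrate_code(base_donor.base, tail_donor.n_phosphates),
        atoms=atoms,
        analog_bridge=tail_donor.analog_bridge,
        seq_id=tail_donor.seq_id,
        chain=tail_donor.chain,
    )
    c1 = out.get("C1'")
    gn = out.get(out.glycosidic_nitrogen)
    if c1 is None or gn is None:
        raise GeometryError("hybrid lost its glycosidic atoms")
    bond = float(np.linalg.norm(c1.coord - gn.coord))
    if not 1.2 <= bond <= 1.8:
        raise GeometryError(
            f"glycosidic C1'-{out.glycosidic_nitrogen} distance {bond:.2f} A "
            "outside 1.2-1.8 A: fragments are not chemically bonded")
    return out


# --- conserved-water selection ----------------------------------------------

def _water_oxygen(res: Residue) -> Atom | None:
    for atom in res.atoms:
        if atom.element.upper() == "O":
            return atom
    return None


def _terminal_phosphorus(substrate: NucleotideLigand) -> Atom:
    for name in ("PG", "PB", "PA"):
        atom = substrate.get(name)
        if atom is not None:
            return atom
    raise InputError("substrate has no phosphorus atom")


def _terminal_oxygens(substrate: NucleotideLigand) -> list[Atom]:
    group = "G" if substrate.get("PG") is not None else "B"
    names = [f"O1{group}", f"O2{group}", f"O3{group}", f"N3{group}"]
    return [a for n in names if (a := substrate.get(n)) is not None]


def select_site_waters(source: Structure, cofactor: Atom,
                       substrate: NucleotideLigand,
                       shell_cutoff: float = 3.2,
                       terminal_cutoff: float = 4.0) -> SiteWaters:
    """Pick the six conserved waters of a productive complex.

    Shell: water oxygens within ``shell_cutoff`` of the cofactor (four
    expected in a well-resolved complex).  Catalytic: the nearest non-shell
    water to the terminal phosphorus (the attacking-water position).
    Terminal: the nearest remaining water within ``terminal_cutoff`` of the
    last phosphate group's oxygens.  All choices are deterministic -
    distance first, lowest serial as tie-break - and invariant under water
    record order.
    """
    waters: list[tuple[Residue, Atom]] = []
    for _, res in source.residues():
        if res.is_water:
            oxy = _water_oxygen(res)
            if oxy is not None:
                waters.append((res, oxy))
    result = SiteWaters()
    if not waters:
        result.warnings.append("source contains no waters; selection incomplete")
        return result

    def keyed(dist: float, atom: Atom) -> tuple[float, int]:
        return (round(dist, 6), atom.serial)

    shell = sorted(
        ((res, oxy, float(np.linalg.norm(oxy.coord - cofactor.coord)))
         for res, oxy in waters),
        key=lambda t: keyed(t[2], t[1]))
    shell = [(res, oxy) for res, oxy, d in shell if d <= shell_cutoff]
    result.shell = [res.copy() for res, _ in shell]
    if len(result.shell) < 4:
        result.warnings.append(
            f"only {len(result.shell)} first-shell waters within "
            f"{shell_cutoff:.2f} A of the cofactor (4 expected)")
    shell_ids = {id(res) for res, _ in shell}
    remaining = [(res, oxy) for res, oxy in waters if id(res) not in shell_ids]

    term_p = _terminal_phosphorus(substrate)
    if remaining:
        res, oxy = min(remaining,
                       key=lambda t: keyed(float(np.linalg.norm(t[1].coord - term_p.coord)),
                                           t[1]))
        result.catalytic = res.copy()
        remaining = [(r, o) for r, o in remaining if id(r) != id(res)]
    else:
        result.warnings.append("no candidate catalytic water")

    term_os = _terminal_oxygens(substrate)
    if remaining and term_os:
        def odist(oxy: Atom) -> float:
            return min(float(np.linalg.norm(oxy.coord - a.coord)) for a in term_os)
        candidates = [(res, oxy, odist(oxy)) for res, oxy in remaining]
        candidates = [(r, o, d) for r, o, d in candidates if d <= terminal_cutoff]
        if candidates:
            res, oxy, _ = min(candidates, key=lambda t: keyed(t[2], t[1]))
            result.terminal = res.copy()
        else:
            result.warnings.append(
                f"no water within {terminal_cutoff:.2f} A of the terminal phosphate")
    elif not remaining:
        result.warnings.append("no candidate terminal-phosphate water")
    return result


# --- grafting ----------------------------------------------------------------

def graft_complex(target_model: Structure, source_complex: Structure,
                  superposition: SuperpositionResult,
                  substrate: NucleotideLigand | None = None,
                  cofactor: Atom | None = None,
                  waters: SiteWaters | None = None,
                  graft_chain: str = "X") -> GraftedComplex:
    """Transplant the substrate bundle into the target frame.

    Every selected component (substrate, cofactor ion, conserved waters)
    is mapped by the protein superposition transform and inserted into a
    copy of the target as residues of a dedicated chain with fresh
    serials.  The bundle moves as one rigid body, so all distances inside
    it are preserved.  Provenance records the source and the transform.
    """
    if substrate is None and cofactor is None and waters is None:
        substrate, cofactor, waters = _auto_components(source_complex)
    transform = superposition.transform
    out = target_model.copy()
    max_serial = max((a.serial for a in out.atoms()), default=0)
    max_seq = max((r.seq_id for _, r in out.residues()), default=0)
    grafted: list[Residue] = []
    seq = max_seq

    moved_substrate = substrate.transformed(transform) if substrate else None
    if moved_substrate is not None:
        seq += 1
        res = moved_substrate.to_residue()
        res.seq_id = seq
        grafted.append(res)
        moved_substrate.seq_id = seq
        moved_substrate.chain = graft_chain
    moved_cofactor = None
    if cofactor is not None:
        moved_cofactor = cofactor.copy()
        moved_cofactor.coord = transform.apply(moved_cofactor.coord)
        seq += 1
        grafted.append(Residue(moved_cofactor.element.upper(), seq, "",
                               [moved_cofactor]))
    moved_waters = waters.transformed(transform) if waters else SiteWaters()
    for water in moved_waters.all_waters():
        seq += 1
        res = water.copy()
        res.seq_id = seq
        grafted.append(res)

    for res in grafted:
        for atom in res.atoms:
            max_serial += 1
            atom.serial = max_serial
    out.chains.setdefault(graft_chain, []).extend(grafted)

    provenance = {
        "source": source_complex.id,
        "source_path": source_complex.source,
        "transform": transform.to_dict(),
        "superposition_rmsd": superposition.rmsd,
        "retained_pairs": superposition.retained_pairs,
        "components": {
            "substrate": substrate.comp_id if substrate else None,
            "cofactor": cofactor.element.upper() if cofactor else None,
            "n_waters": len(moved_waters.all_waters()),
        },
        "graft_chain": graft_chain,
    }
    return GraftedComplex(target=out, substrate=moved_substrate,
                          cofactor=moved_cofactor, waters=moved_waters,
                          provenance=provenance)


def identify_components(structure: Structure
                        ) -> tuple[NucleotideLigand, Atom | None, SiteWaters]:
    """Locate the single nucleotide, metal cofactor and site waters."""
    return _auto_components(structure)


def _auto_components(structure: Structure
                     ) -> tuple[NucleotideLigand, Atom | None, SiteWaters]:
    substrate = extract_component(structure, Selector(category="ligand"))
    metals = [res.atoms[0] for _, res in structure.residues() if res.is_metal]
    cofactor = metals[0] if metals else None
    if cofactor is not None:
        waters = select_site_waters(structure, cofactor, substrate)
    else:
        waters = SiteWaters(warnings=["no metal cofactor found"])
    return substrate, cofactor, waters
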