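"""Structure I/O and atom selection.

A deliberately small hierarchical model (``Structure`` -> chains ->
``Residue`` -> ``Atom``) holding orthogonal coordinates in Angstrom.
Reading and writing of PDB/mmCIF files is delegated to gemmi; this layer
normalizes what the downstream geometry needs to be deterministic:

* only the first model of multi-model files is kept;
* alternate locations are resolved to a single conformer per atom name
  (highest occupancy, ties broken by the lexicographically smallest
  altloc indicator);
* water components are normalized to ``HOH``; metals are single-atom
  residues recognized by element.

Author residue numbering is preserved; coordinates are never re-framed.
"""

from __future__ import annotations

import copy
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import gemmi
import numpy as np

from . import nomenclature as nom
from .errors import (
    FormatError,
    NetworkError,
    ParseError,
    SerializationError,
)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Selector",
    "read_structure",
    "write_structure",
    "select_atoms",
    "fetch_reference",
    "polymer_residues",
]


@dataclass
class Atom:
    """A single atom: PDB-style name, element symbol and position in A."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float = 0.0
    serial: int = 1

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


@dataclass
class Residue:
    """A chemical component instance (amino acid, ligand, water or metal)."""

    comp_id: str
    seq_id: int
    ins_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def get(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    @property
    def is_water(self) -> bool:
        return self.comp_id in nom.WATER_CODES

    @property
    def is_metal(self) -> bool:
        return (len(self.atoms) == 1
                and self.atoms[0].element.upper() in nom.METAL_ELEMENTS)

    @property
    def is_polymer(self) -> bool:
        return self.comp_id in nom.AA_THREE_TO_ONE

    @property
    def category(self) -> str:
        if self.is_water:
            return "water"
        if self.is_metal:
            return "metal"
        if self.is_polymer:
            return "polymer"
        return "ligand"

    def copy(self) -> "Residue":
        return Residue(self.comp_id, self.seq_id, self.ins_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Structure:
    """Named, ordered chains of residues."""

    id: str
    chains: dict[str, list[Residue]]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a Structure needs at least one chain")

    def residues(self) -> Iterator[tuple[str, Residue]]:
        for chain_name, residues in self.chains.items():
            for res in residues:
                yield chain_name, res

    def atoms(self) -> Iterator[Atom]:
        for _, res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms()], dtype=float)

    def copy(self) -> "Structure":
        return Structure(self.id,
                         {c: [r.copy() for r in rs] for c, rs in self.chains.items()},
                         self.source)


@dataclass
class Selector:
    """Conjunction of residue-level filters; an empty selector matches all."""

    chains: Sequence[str] | None = None
    comp_ids: Sequence[str] | None = None
    seq_range: tuple[int, int] | None = None
    category: str | None = None  # polymer | ligand | water | metal

    def matches(self, chain_name: str, residue: Residue) -> bool:
        if self.chains is not None and chain_name not in self.chains:
            return False
        if self.comp_ids is not None and residue.comp_id not in self.comp_ids:
            return False
        if self.seq_range is not None:
            lo, hi = self.seq_range
            if not lo <= residue.seq_id <= hi:
                return False
        if self.category is not None and residue.category != self.category:
            return False
        return True


# --- altloc resolution ------------------------------------------------------

def _resolve_altlocs(atoms: Iterable[Atom]) -> list[Atom]:
    """One conformer per atom name: highest occupancy, tie -> smallest altloc."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
            continue
        cur = best[atom.name]
        if (atom.occupancy > cur.occupancy
                or (atom.occupancy == cur.occupancy and atom.altloc < cur.altloc)):
            best[atom.name] = atom
    resolved = []
    for name in order:
        atom = best[name].copy()
        atom.altloc = ""
        resolved.append(atom)
    return resolved


# --- reading ----------------------------------------------------------------

def _detect_format(path: Path, format: str) -> str:
    if format in ("pdb", "mmcif"):
        return format
    if format != "auto":
        raise FormatError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    # sniff: mmCIF files start with "data_"
    with open(path, "r", errors="replace") as fh:
        head = fh.read(2048)
    if head.lstrip().startswith("data_"):
        return "mmcif"
    if any(head.startswith(r) or f"\n{r}" in head
           for r in ("ATOM", "HETATM", "HEADER", "CRYST1", "MODEL", "REMARK")):
        return "pdb"
    raise FormatError(f"cannot determine format of {path}")


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a normalized :class:`Structure`.

    Only the first model is kept; altlocs are resolved (highest occupancy,
    tie -> smallest altloc indicator); water components are renamed to HOH.
    Hydrogens are retained if present.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    serial = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            comp_id = res.name.strip().upper()
            if comp_id in nom.WATER_CODES:
                comp_id = "HOH"
            raw = []
            for atom in res:
                serial += 1
                raw.append(Atom(
                    name=atom.name.strip(),
                    element=atom.element.name.upper() or "X",
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                    b_iso=atom.b_iso,
                    serial=atom.serial if atom.serial > 0 else serial,
                ))
            if not raw:
                continue
            residues.append(Residue(
                comp_id=comp_id,
                seq_id=res.seqid.num,
                ins_code=(res.seqid.icode or "").strip(),
                atoms=_resolve_altlocs(raw),
            ))
        if residues:
            chains.setdefault(chain.name, []).extend(residues)
    if not chains:
        raise ParseError(f"{path}: no atoms found")
    return Structure(id=path.stem, chains=chains, source=str(path))


# --- writing ----------------------------------------------------------------

def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    serial = 0
    for chain_name, residues in structure.chains.items():
        chain = gemmi.Chain(chain_name)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.comp_id
            gres.seqid = gemmi.SeqId(res.seq_id, res.ins_code or " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise SerializationError(
                        f"atom name {atom.name!r} exceeds the 4-character PDB field")
                serial += 1
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element.capitalize())
                gatom.pos = gemmi.Position(*atom.coord)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_iso
                gatom.serial = serial
                gres.add_atom(gatom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a structure as PDB or mmCIF (coordinates to 0.001 A in PDB)."""
    if structure.n_atoms == 0:
        raise SerializationError("refusing to write an empty structure")
    if format not in ("pdb", "mmcif"):
        raise FormatError(f"unknown output format {format!r}")
    st = _to_gemmi(structure)
    path = Path(path)
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# --- selection --------------------------------------------------------------

def select_atoms(structure: Structure, selector: Selector) -> Structure:
    """Project a structure onto the residues matching every filter conjunct.

    The input is untouched; chains that end up empty are dropped.  An empty
    result is legal and is returned as a Structure with one empty chain
    placeholder removed lazily by callers checking ``n_atoms``.
    """
    chains: dict[str, list[Residue]] = {}
    for chain_name, residues in structure.chains.items():
        kept = [r.copy() for r in residues if selector.matches(chain_name, r)]
        if kept:
            chains[chain_name] = kept
    if not chains:
        # keep the Structure invariant (>= 1 chain) with an empty chain
        first = next(iter(structure.chains))
        chains = {first: []}
    return Structure(id=structure.id, chains=chains, source=structure.source)


def polymer_residues(structure: Structure, chain: str | None = None) -> list[Residue]:
    """Ordered polymer residues, optionally restricted to one chain."""
    out = []
    for chain_name, res in structure.residues():
        if chain is not None and chain_name != chain:
            continue
        if res.is_polymer:
            out.append(res)
    return out


# --- remote retrieval -------------------------------------------------------

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def _default_downloader(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover
        return resp.read()


def fetch_reference(pdb_id: str, cache_dir: str | Path,
                    downloader: Callable[[str], bytes] | None = None) -> Structure:
    """Return a PDB entry, downloading into ``cache_dir`` at most once.

    A file already present in the cache is reused without network access.
    When offline and uncached, a :class:`NetworkError` explains how to place
    the file manually.
    """
    pdb_id = pdb_id.strip().upper()
    if len(pdb_id) != 4:
        raise FormatError(f"{pdb_id!r} is not a 4-character PDB accession")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cached = cache_dir / f"{pdb_id}.pdb"
    if not cached.exists():
        url = _RCSB_URL.format(pdb_id=pdb_id)
        fetch = downloader or _default_downloader
        try:
            payload = fetch(url)
        except Exception as exc:
            raise NetworkError(
                f"could not retrieve {pdb_id} from {url} ({exc}); "
                f"place the file manually at {cached} to work offline"
            ) from exc
        cached.write_bytes(payload)
    return read_structure(cached, format="auto")
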