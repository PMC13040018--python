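"""Hierarchical coordinate model and PDB/mmCIF I/O.

The in-memory model is a plain chains -> residues -> atoms hierarchy keyed by
*author* numbering (chain id, residue number, insertion code), because every
residue range in this package — the EGFR 287–302 epitope loop, the receptor
domain boundaries, CDR windows — is stated in author coordinates.  Parsing and
writing go through :mod:`gemmi`; this module only fixes the policies the
analysis depends on (single conformer, heavy atoms, waters out).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueID",
    "Chain",
    "AtomicStructure",
    "StructureError",
    "ChainNotFoundError",
    "EmptyStructureError",
    "AtomNotFoundError",
    "read_structure",
    "write_structure",
    "select_region",
    "truncate_n_terminal",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(Exception):
    """Base error for coordinate-model problems."""


class ChainNotFoundError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class AtomNotFoundError(StructureError):
    pass


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with author metadata.

    ``coords`` are Cartesian, in Å.  ``altloc`` is blank after the default
    single-conformer reduction (highest occupancy wins, ties alphabetical).
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")

    def copy(self) -> "Atom":
        return dataclasses.replace(self, coords=self.coords.copy())


@dataclass(frozen=True)
class ResidueID:
    """Author-coordinate residue identity: (chain, number, insertion code)."""

    chain_id: str
    seq_num: int
    icode: str = ""
    res_name: str = ""

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_num}{self.icode}"


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def rid(self) -> ResidueID:
        return ResidueID(self.chain_id, self.seq_num, self.icode, self.res_name)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def get_atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise AtomNotFoundError(f"atom {name!r} not found in residue {self.rid}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_num, self.res_name, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if not r.is_water())

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class AtomicStructure:
    """Ordered chains of ordered residues; the substrate for all geometry."""

    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    disulfides: list[tuple[ResidueID, ResidueID]] = field(default_factory=list)

    # -- iteration / accessors -------------------------------------------------
    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ChainNotFoundError(
            f"chain {chain_id!r} not present (have {self.chain_ids})")

    def residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array in iteration order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for _, a in self.atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise StructureError(f"coordinate array shape {xyz.shape} != ({self.n_atoms}, 3)")
        for (_, a), row in zip(self.atoms(), xyz):
            a.coords = row.copy()

    def copy(self) -> "AtomicStructure":
        return AtomicStructure([c.copy() for c in self.chains],
                               dict(self.metadata), list(self.disulfides))

    def validate(self) -> None:
        """Enforce identity invariants: unique residue IDs and atom triples."""
        seen_res: set[tuple[str, int, str]] = set()
        for r in self.residues():
            k = r.rid.key()
            if k in seen_res:
                raise StructureError(f"duplicate residue identity {r.rid}")
            seen_res.add(k)
            seen_at: set[tuple[str, str]] = set()
            for a in r.atoms:
                ak = (a.name, a.altloc)
                if ak in seen_at:
                    raise StructureError(f"duplicate atom {a.name}/{a.altloc!r} in {r.rid}")
                seen_at.add(ak)


# ---------------------------------------------------------------------------
# reading


def _reduce_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first altloc
    alphabetically.  The kept atom's altloc is blanked."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        chosen = group[0]
        chosen.altloc = ""
        out.append(chosen)
    return out


def read_structure(path: str | Path, format: str | None = None, *,
                   model_index: int = 0,
                   exclude_water: bool = True,
                   exclude_hydrogens: bool = True,
                   keep_altlocs: bool = False) -> AtomicStructure:
    """Read a PDB or mmCIF file into an :class:`AtomicStructure`.

    Parameters
    ----------
    path : file path.
    format : ``"pdb"`` or ``"mmcif"``; inferred from the suffix when None.
    model_index : which NMR/multi-model block to take (X-ray files have one).
    exclude_water, exclude_hydrogens : drop waters / H atoms (default; the
        downstream geometry assumes heavy atoms of a single conformer).
    keep_altlocs : retain all alternate conformers instead of reducing to the
        highest-occupancy one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    try:
        if format == "mmcif":
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc
    gst.setup_entities()

    if len(gst) == 0:
        raise EmptyStructureError(f"{path}: no models")
    gmodel = gst[model_index]

    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if exclude_water and gres.name in WATER_NAMES:
                continue
            icode = gres.seqid.icode.strip()
            atoms: list[Atom] = []
            for ga in gres:
                if exclude_hydrogens and ga.element.is_hydrogen:
                    continue
                atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(float(ga.occ), 0.0), 1.0),
                    b_factor=float(ga.b_iso),
                    altloc=(ga.altloc or "").strip(),
                ))
            if not keep_altlocs:
                atoms = _reduce_altlocs(atoms)
            if atoms:
                residues.append(Residue(gchain.name, gres.seqid.num,
                                        gres.name, icode, atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))

    st = AtomicStructure(chains, metadata={
        "accession": (gst.name or "").strip(),
        "title": dict(gst.info).get("_struct.title", ""),
        "source_path": str(path),
    })
    # disulfides from explicit connection records, where present
    for con in gst.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            a, b = con.partner1, con.partner2
            st.disulfides.append((
                ResidueID(a.chain_name, a.res_id.seqid.num,
                          a.res_id.seqid.icode.strip(), a.res_id.name),
                ResidueID(b.chain_name, b.res_id.seqid.num,
                          b.res_id.seqid.icode.strip(), b.res_id.name),
            ))
    if st.n_atoms == 0:
        raise EmptyStructureError(f"{path}: structure contains zero atoms")
    st.validate()
    return st


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(structure: AtomicStructure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.metadata.get("accession", "") or "EPIF"
    gmodel = gemmi.Model("1")
    for chain in structure.chains:
        if len(chain.chain_id) > 2:
            raise StructureError(f"chain id {chain.chain_id!r} unrepresentable in PDB")
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise StructureError(f"atom name {atom.name!r} exceeds 4 characters")
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                ga.altloc = atom.altloc[:1] if atom.altloc else "\0"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    gst.add_model(gmodel)
    return gst


def write_structure(structure: AtomicStructure, path: str | Path,
                    format: str = "pdb") -> None:
    """Write the structure as a standard PDB file (0.001 Å coordinate grid)."""
    if structure.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    if format != "pdb":
        raise ValueError(f"only PDB output is supported, not {format!r}")
    gst = _to_gemmi(structure)
    gst.setup_entities()
    gst.write_pdb(str(Path(path)))


# ---------------------------------------------------------------------------
# selection & truncation


def select_region(structure: AtomicStructure,
                  chain_ids: Iterable[str] | None = None,
                  residue_range: tuple[int, int] | None = None,
                  atom_names: Iterable[str] | None = None,
                  exclude_water: bool = True) -> AtomicStructure:
    """Return a new structure holding exactly the atoms matching every filter.

    ``residue_range`` is inclusive ``(lo, hi)`` in author numbering.  An empty
    result is allowed (flagged in ``metadata["empty_selection"]``); naming a
    chain the structure does not have is an error.
    """
    if structure.n_atoms == 0:
        raise EmptyStructureError("cannot select from an empty structure")
    chain_set = set(chain_ids) if chain_ids is not None else None
    if chain_set is not None:
        missing = chain_set - set(structure.chain_ids)
        if missing:
            raise ChainNotFoundError(
                f"unknown chain(s) {sorted(missing)}; structure has {structure.chain_ids}")
    if residue_range is not None:
        lo, hi = residue_range
        if lo > hi:
            raise ValueError(f"residue range lo {lo} > hi {hi}")
    name_set = set(atom_names) if atom_names is not None else None

    out_chains: list[Chain] = []
    for chain in structure.chains:
        if chain_set is not None and chain.chain_id not in chain_set:
            continue
        kept: list[Residue] = []
        for res in chain.residues:
            if exclude_water and res.is_water():
                continue
            if residue_range is not None and not (residue_range[0] <= res.seq_num <= residue_range[1]):
                continue
            atoms = [a.copy() for a in res.atoms
                     if name_set is None or a.name in name_set]
            if atoms:
                kept.append(Residue(res.chain_id, res.seq_num, res.res_name,
                                    res.icode, atoms))
        if kept:
            out_chains.append(Chain(chain.chain_id, kept))

    out = AtomicStructure(out_chains, dict(structure.metadata))
    out.metadata["empty_selection"] = out.n_atoms == 0
    kept_rids = {r.rid.key() for r in out.residues()}
    out.disulfides = [(a, b) for a, b in structure.disulfides
                      if a.key() in kept_rids and b.key() in kept_rids]
    return out


def truncate_n_terminal(structure: AtomicStructure, chain_id: str,
                        cut_after: int) -> AtomicStructure:
    """Remove every residue with seq_num <= ``cut_after`` from one chain.

    ``cut_after=0`` (or anything below the first residue) is the identity.
    Removing the whole chain is an error.
    """
    chain = structure.chain(chain_id)  # raises ChainNotFoundError
    out = structure.copy()
    target = out.chain(chain_id)
    target.residues = [r for r in target.residues if r.seq_num > cut_after]
    if not target.residues:
        raise StructureError(
            f"cut_after={cut_after} removes all {len(chain)} residues of chain {chain_id!r}")
    kept_rids = {r.rid.key() for r in out.residues()}
    out.disulfides = [(a, b) for a, b in out.disulfides
                      if a.key() in kept_rids and b.key() in kept_rids]
    return out
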