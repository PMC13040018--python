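"""Geometric detection and typing of epitope–paratope interactions.

Classification uses heavy-atom distance criteria only — the kind of crystal
structure this targets (mid-2 Å resolution) carries no hydrogens, so
donor–H–acceptor angle tests are deliberately out of scope:

* hydrogen bond: polar heavy atoms (N/O/S) within the H-bond cutoff
  (default 3.5 Å);
* ionic (salt bridge): side-chain carboxylate oxygen of Asp/Glu against a
  cationic nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) within 4.0 Å;
* cation-π: cationic nitrogen against any aromatic-ring atom of
  Phe/Tyr/Trp/His within 4.5 Å.

A pair that satisfies a stronger rule is reported once with the stronger
type (precedence ionic > cation-π > H-bond).  CDR attribution is purely a
configured residue-range lookup; no numbering scheme is implemented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    Atom,
    AtomicStructure,
    AtomNotFoundError,
    BACKBONE_ATOMS,
    Residue,
    StructureError,
)

__all__ = [
    "ContactRecord",
    "CdrMap",
    "ContactCutoffs",
    "measure_distance",
    "classify_contacts",
    "interface_table",
]

CARBOXYLATE_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
CATIONIC_N = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}}
AROMATIC_RING = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
POLAR_ELEMENTS = {"N", "O", "S"}


@dataclass(frozen=True)
class ContactCutoffs:
    """Distance cutoffs (Å) per interaction type."""

    h_bond: float = 3.5
    ionic: float = 4.0
    cation_pi: float = 4.5

    def __post_init__(self) -> None:
        if min(self.h_bond, self.ionic, self.cation_pi) <= 0:
            raise ValueError("cutoffs must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(self.h_bond, self.ionic, self.cation_pi)


@dataclass
class CdrMap:
    """Configured CDR residue windows: {chain_role: [(label, (lo, hi)), ...]}."""

    ranges: dict[str, list[tuple[str, tuple[int, int]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, windows in self.ranges.items():
            spans = sorted((lo, hi, lab) for lab, (lo, hi) in windows)
            for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"CDR ranges {l1} and {l2} overlap on chain role {role!r}")

    def label(self, chain_role: str, seq_num: int) -> str | None:
        for lab, (lo, hi) in self.ranges.get(chain_role, []):
            if lo <= seq_num <= hi:
                return lab
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "CdrMap":
        ranges = {role: [(lab, (int(lo), int(hi)))
                         for lab, (lo, hi) in
                         (windows.items() if isinstance(windows, dict) else windows)]
                  for role, windows in d.items()}
        return cls(ranges)


@dataclass
class ContactRecord:
    """One typed epitope–paratope atom-pair interaction (a Table row)."""

    epitope_residue: str
    epitope_atom: str
    partner_residue: str
    partner_atom: str
    partner_chain_role: str
    distance: float
    interaction_type: str  # h_bond | ionic | cation_pi
    cdr: str | None = None
    epitope_mainchain: bool = False
    partner_mainchain: bool = False
    epitope_seq_num: int = 0
    partner_seq_num: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "epitope_residue", "epitope_atom", "partner_residue", "partner_atom",
            "partner_chain_role", "distance", "interaction_type", "cdr",
            "epitope_mainchain", "partner_mainchain")}


# ---------------------------------------------------------------------------


def measure_distance(structure: AtomicStructure,
                     atom_a: tuple[str, int, str],
                     atom_b: tuple[str, int, str]) -> float:
    """Euclidean distance (Å) between two atoms given as (chain, resnum, atom)."""

    def locate(spec: tuple[str, int, str]) -> Atom:
        chain_id, seq_num, name = spec
        chain = structure.chain(chain_id)
        for res in chain:
            if res.seq_num == seq_num and res.has_atom(name):
                return res.get_atom(name)
        raise AtomNotFoundError(f"atom {name!r} of residue {seq_num} "
                                f"in chain {chain_id!r} not found")

    a, b = locate(atom_a), locate(atom_b)
    return float(np.linalg.norm(a.coords - b.coords))


def _is_polar(res: Residue, atom: Atom) -> bool:
    return atom.element.upper() in POLAR_ELEMENTS


def _is_carboxylate_o(res: Residue, atom: Atom) -> bool:
    return atom.name in CARBOXYLATE_O.get(res.res_name, ())


def _is_cationic_n(res: Residue, atom: Atom) -> bool:
    return atom.name in CATIONIC_N.get(res.res_name, ())


def _is_ring_atom(res: Residue, atom: Atom) -> bool:
    return atom.name in AROMATIC_RING.get(res.res_name, ())


def classify_pair(res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom,
                  distance: float, cutoffs: ContactCutoffs) -> str | None:
    """Type one atom pair, honouring precedence ionic > cation-π > H-bond."""
    ionic = ((_is_carboxylate_o(res_a, atom_a) and _is_cationic_n(res_b, atom_b))
             or (_is_cationic_n(res_a, atom_a) and _is_carboxylate_o(res_b, atom_b)))
    if ionic and distance <= cutoffs.ionic:
        return "ionic"
    catpi = ((_is_cationic_n(res_a, atom_a) and _is_ring_atom(res_b, atom_b))
             or (_is_ring_atom(res_a, atom_a) and _is_cationic_n(res_b, atom_b)))
    if catpi and distance <= cutoffs.cation_pi:
        return "cation_pi"
    if (_is_polar(res_a, atom_a) and _is_polar(res_b, atom_b)
            and distance <= cutoffs.h_bond):
        return "h_bond"
    return None


def classify_contacts(complex_structure: AtomicStructure,
                      epitope_group: AtomicStructure,
                      antibody_groups: dict[str, AtomicStructure],
                      cdr_map: CdrMap | None = None,
                      cutoffs: ContactCutoffs | None = None
                      ) -> list[ContactRecord]:
    """Enumerate typed epitope–antibody contacts.

    ``epitope_group`` and each entry of ``antibody_groups`` (keyed by chain
    role, e.g. ``heavy``/``light``) are selections of ``complex_structure``
    (or free-standing structures in the same frame).  Groups must be disjoint.
    Returns one record per qualifying atom pair, ordered by epitope residue
    number, then partner role, then distance.
    """
    cutoffs = cutoffs or ContactCutoffs()
    cdr_map = cdr_map or CdrMap()
    ep_atoms = list(epitope_group.atoms())
    if not ep_atoms:
        raise StructureError("epitope group is empty")

    ep_keys = {(r.chain_id, r.seq_num, r.icode, a.name) for r, a in ep_atoms}
    records: list[ContactRecord] = []
    ep_xyz = np.array([a.coords for _, a in ep_atoms])
    tree = cKDTree(ep_xyz)

    for role, group in antibody_groups.items():
        g_atoms = list(group.atoms())
        for r, a in g_atoms:
            if (r.chain_id, r.seq_num, r.icode, a.name) in ep_keys:
                raise StructureError(
                    f"antibody group {role!r} overlaps the epitope group at {r.rid}")
        if not g_atoms:
            continue
        g_xyz = np.array([a.coords for _, a in g_atoms])
        g_tree = cKDTree(g_xyz)
        neighbour_lists = tree.query_ball_tree(g_tree, cutoffs.max_cutoff)
        for i, js in enumerate(neighbour_lists):
            res_e, atom_e = ep_atoms[i]
            for j in js:
                res_p, atom_p = g_atoms[j]
                d = float(np.linalg.norm(atom_e.coords - atom_p.coords))
                itype = classify_pair(res_e, atom_e, res_p, atom_p, d, cutoffs)
                if itype is None:
                    continue
                records.append(ContactRecord(
                    epitope_residue=f"{res_e.one_letter}{res_e.seq_num}",
                    epitope_atom=atom_e.name,
                    partner_residue=f"{res_p.one_letter}{res_p.seq_num}",
                    partner_atom=atom_p.name,
                    partner_chain_role=role,
                    distance=round(d, 2),
                    interaction_type=itype,
                    cdr=cdr_map.label(role, res_p.seq_num),
                    epitope_mainchain=atom_e.name in BACKBONE_ATOMS,
                    partner_mainchain=atom_p.name in BACKBONE_ATOMS,
                    epitope_seq_num=res_e.seq_num,
                    partner_seq_num=res_p.seq_num,
                ))

    records.sort(key=lambda r: (r.epitope_seq_num, r.epitope_atom,
                                r.partner_chain_role, r.distance,
                                r.partner_seq_num, r.partner_atom))
    return records


def _atom_label(residue: str, atom: str, mainchain: bool) -> str:
    star = "*" if mainchain else ""
    return f"{residue} ({atom}{star})"


def interface_table(records: list[ContactRecord], fmt: str = "tsv") -> str:
    """Render contact records as a delimited table or JSON.

    Main-chain atoms carry the conventional asterisk (e.g. ``D297 (O*)``);
    ordering is deterministic (epitope residue, partner chain, distance).
    """
    rows = []
    for r in sorted(records, key=lambda r: (r.epitope_seq_num,
                                            r.partner_chain_role, r.distance)):
        rows.append({
            "epitope": _atom_label(r.epitope_residue, r.epitope_atom, r.epitope_mainchain),
            "partner": _atom_label(r.partner_residue, r.partner_atom, r.partner_mainchain),
            "chain": r.partner_chain_role,
            "cdr": r.cdr or "",
            "distance_A": f"{r.distance:.2f}",
            "interaction": r.interaction_type,
        })
    if fmt == "json":
        return json.dumps(rows, indent=2)
    header = ["epitope", "partner", "chain", "cdr", "distance_A", "interaction"]
    lines = ["\t".join(header)]
    lines += ["\t".join(row[h] for h in header) for row in rows]
    return "\n".join(lines) + "\n"
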