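"""Graft-and-clash epitope-accessibility modelling.

The question this module answers: can an antibody Fab that binds an epitope
peptide in isolation physically reach the same epitope when it sits inside a
full receptor ectodomain?  The procedure transplants ("grafts") the Fab from
its peptide complex into the receptor frame by superposing the bound peptide
hairpin onto the receptor's copy of the epitope, then counts van der Waals
overlaps between the grafted Fab and the rest of the receptor.  Severe,
widespread overlap means the conformation occludes the epitope; few or no
overlaps mean the epitope is antibody-accessible.  A truncated-receptor
variant (the EGFRvIII-style deletion removing the ectodomain's N-terminal
273 residues) is built by chain truncation and assessed the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .sasa import SasaParams, VDW_RADII
from .structures import AtomicStructure, StructureError, select_region, truncate_n_terminal
from .superpose import SuperpositionResult, apply_transform, kabsch_superpose, pair_atoms

__all__ = [
    "DomainMap",
    "ClashReport",
    "AccessibilityCall",
    "GraftResult",
    "DEFAULT_DOMAIN_MAP",
    "graft_fab",
    "count_clashes",
    "classify_accessibility",
    "build_egfrviii_model",
]


@dataclass
class DomainMap:
    """Named inclusive residue ranges for receptor domains (non-overlapping)."""

    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted((lo, hi, name) for name, (lo, hi) in self.ranges.items())
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"domain ranges {n1!r} and {n2!r} overlap")

    def domain_of(self, seq_num: int) -> str:
        for name, (lo, hi) in self.ranges.items():
            if lo <= seq_num <= hi:
                return name
        return "unmapped"


# EGFR ectodomain subdomains, author numbering of the mature receptor
DEFAULT_DOMAIN_MAP = DomainMap({
    "I": (1, 164),
    "II": (165, 310),
    "III": (311, 480),
    "IV": (481, 618),
})


@dataclass
class GraftResult:
    """A Fab placed in the receptor frame, plus how well the hairpin aligned."""

    fab: AtomicStructure
    transform: SuperpositionResult
    alignment_rmsd: float
    rmsd_warning: bool = False


@dataclass
class ClashReport:
    """Census of inter-structure van der Waals overlaps after a graft."""

    n_clashes: int
    per_domain: dict[str, int]
    per_chain: dict[str, int]
    worst_overlap: float
    overlap_tolerance: float
    radii_set: str
    excluded_epitope: tuple[int, int] | None = None
    frames_disjoint: bool = False
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_clashes": self.n_clashes,
            "per_domain": self.per_domain,
            "per_chain": self.per_chain,
            "worst_overlap_A": self.worst_overlap,
            "overlap_tolerance_A": self.overlap_tolerance,
            "radii_set": self.radii_set,
            "excluded_epitope": list(self.excluded_epitope) if self.excluded_epitope else None,
            "frames_disjoint": self.frames_disjoint,
        }


@dataclass
class AccessibilityCall:
    """Pure threshold function of the clash count."""

    label: str  # accessible | partial | inaccessible
    n_clashes: int
    accessible_max: int
    inaccessible_min: int


# ---------------------------------------------------------------------------


def graft_fab(fab_complex: AtomicStructure,
              receptor: AtomicStructure,
              peptide_chain: str,
              receptor_chain: str,
              epitope_range: tuple[int, int] = (287, 302),
              hairpin_range: tuple[int, int] = (293, 302),
              atom_set: str = "backbone",
              rmsd_ceiling: float = 3.0) -> GraftResult:
    """Transplant the Fab onto a receptor conformation via the shared epitope.

    The bound peptide's hairpin residues (``hairpin_range``, restricted to
    ``epitope_range`` context on the receptor side) are superposed onto the
    receptor's copy; the resulting rigid transform is applied to the *entire*
    Fab (all chains of the complex except the peptide), which is returned in
    the receptor frame with the peptide dropped.
    """
    hairpin = select_region(fab_complex, chain_ids=[peptide_chain],
                            residue_range=hairpin_range)
    target = select_region(receptor, chain_ids=[receptor_chain],
                           residue_range=hairpin_range)
    pairing = pair_atoms(hairpin, target, "by-seqnum", atom_set)
    result = kabsch_superpose(pairing)
    warn = result.rmsd > rmsd_ceiling
    if warn:
        warnings.warn(
            f"hairpin alignment rmsd {result.rmsd:.2f} Å exceeds the sanity "
            f"ceiling {rmsd_ceiling:.1f} Å; the grafted pose is unreliable",
            stacklevel=2)
    fab_chains = [c for c in fab_complex.chain_ids if c != peptide_chain]
    if not fab_chains:
        raise StructureError("fab complex contains only the peptide chain")
    fab = select_region(fab_complex, chain_ids=fab_chains)
    fab = apply_transform(fab, result)
    return GraftResult(fab, result, result.rmsd, warn)


def count_clashes(fab: AtomicStructure,
                  receptor: AtomicStructure,
                  exclude_epitope: tuple[int, int] | None = None,
                  domain_map: DomainMap | None = None,
                  overlap_tolerance: float = 0.4,
                  radii_set: str = "bondi",
                  keep_pairs: bool = False) -> ClashReport:
    """Count heavy-atom vdW overlaps between a grafted Fab and a receptor.

    A clash is an inter-structure atom pair with
    ``distance < r_vdw(a) + r_vdw(b) - overlap_tolerance``.  Receptor residues
    inside ``exclude_epitope`` are exempt (the Fab is *supposed* to hug the
    epitope).  Counts are aggregated per receptor domain (via ``domain_map``,
    unmapped residues bucketed as ``"unmapped"``) and per receptor chain.
    Neighbour search is KD-tree based; the result equals the all-pairs
    definition exactly.
    """
    domain_map = domain_map or DomainMap()
    params = SasaParams(radii_set=radii_set)

    rec_atoms = [(r, a) for r, a in receptor.atoms()
                 if not (exclude_epitope is not None
                         and exclude_epitope[0] <= r.seq_num <= exclude_epitope[1])]
    fab_atoms = list(fab.atoms())
    per_domain: dict[str, int] = {}
    per_chain: dict[str, int] = {}
    pairs: list[tuple[str, str, float]] = []
    if not rec_atoms or not fab_atoms:
        return ClashReport(0, per_domain, per_chain, 0.0, overlap_tolerance,
                           radii_set, exclude_epitope)

    table = VDW_RADII[radii_set]
    def radius(atom):  # unknown elements fall back to carbon
        return table.get(atom.element.upper(), table["C"])

    fab_xyz = np.array([a.coords for _, a in fab_atoms])
    rec_xyz = np.array([a.coords for _, a in rec_atoms])
    fab_r = np.array([radius(a) for _, a in fab_atoms])
    rec_r = np.array([radius(a) for _, a in rec_atoms])

    rec_tree = cKDTree(rec_xyz)
    fab_tree = cKDTree(fab_xyz)
    max_pair = fab_r.max() + rec_r.max() - overlap_tolerance

    min_sep = np.inf
    n_clashes = 0
    worst = 0.0
    neighbour_lists = fab_tree.query_ball_tree(rec_tree, max_pair)
    for i, js in enumerate(neighbour_lists):
        for j in js:
            d = float(np.linalg.norm(fab_xyz[i] - rec_xyz[j]))
            cutoff = fab_r[i] + rec_r[j] - overlap_tolerance
            if d < cutoff:
                n_clashes += 1
                overlap = fab_r[i] + rec_r[j] - d
                worst = max(worst, overlap)
                res = rec_atoms[j][0]
                dom = domain_map.domain_of(res.seq_num)
                per_domain[dom] = per_domain.get(dom, 0) + 1
                per_chain[res.chain_id] = per_chain.get(res.chain_id, 0) + 1
                if keep_pairs:
                    pairs.append((f"{fab_atoms[i][0].rid}:{fab_atoms[i][1].name}",
                                  f"{res.rid}:{rec_atoms[j][1].name}", round(d, 3)))

    disjoint = False
    if n_clashes == 0:
        d_min, _ = rec_tree.query(fab_xyz, k=1)
        min_sep = float(np.min(d_min))
        disjoint = min_sep > 50.0
        if disjoint:
            warnings.warn(f"structures are {min_sep:.0f} Å apart; frames look "
                          f"disjoint (was the graft applied?)", stacklevel=2)
    return ClashReport(n_clashes, per_domain, per_chain, round(worst, 3),
                       overlap_tolerance, radii_set, exclude_epitope,
                       disjoint, pairs)


def classify_accessibility(report: ClashReport,
                           accessible_max: int = 10,
                           inaccessible_min: int = 200) -> AccessibilityCall:
    """Map a clash count to accessible / partial / inaccessible."""
    if accessible_max >= inaccessible_min:
        raise ValueError("accessible_max must be below inaccessible_min")
    n = report.n_clashes
    if n <= accessible_max:
        label = "accessible"
    elif n >= inaccessible_min:
        label = "inaccessible"
    else:
        label = "partial"
    return AccessibilityCall(label, n, accessible_max, inaccessible_min)


def build_egfrviii_model(egfr_ectodomain: AtomicStructure,
                         receptor_chain: str,
                         cut_after: int = 273) -> AtomicStructure:
    """Model the exon-2–7 deletion variant by N-terminal chain truncation.

    Removing the ectodomain's first ``cut_after`` residues deletes domain I
    and part of domain II, leaving the remainder of domain II — which carries
    the 287–302 epitope loop — solvent-exposed.
    """
    model = truncate_n_terminal(egfr_ectodomain, receptor_chain, cut_after)
    model.metadata["variant"] = f"N-terminal truncation through residue {cut_after}"
    model.metadata["exposed_epitope_carrier"] = "domain II remainder"
    return model
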