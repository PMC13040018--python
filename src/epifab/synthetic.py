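"""Synthetic structures and sensorgrams with known ground truth.

Every generator is deterministic under (parameters, seed) and ships a
machine-readable truth manifest, so analysis operations can be scored against
construction: a hairpin with a known disulfide geometry, a peptide docked in
a mock two-chain groove with planted typed contacts, a two-structure scene
with an exactly known clash count, and multi-concentration 1:1 sensorgram
sets with known rate constants.  Fixtures are geometric, not energetic —
idealized β-strand spacing and stylized side chains carrying just the
functional atoms (carboxylate oxygens, ammonium/guanidinium nitrogens,
aromatic rings) that contact detection keys on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParams, Sensorgram, simulate_sensorgram
from .structures import (
    Atom,
    AtomicStructure,
    Chain,
    Residue,
    StructureError,
    select_region,
)

__all__ = [
    "make_hairpin",
    "make_groove_complex",
    "make_clash_scene",
    "make_occluded_receptor",
    "make_sensorgram_set",
    "GrooveManifest",
    "ClashSceneError",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# idealized antiparallel β geometry
STRAND_RISE = 3.3        # Å advance per residue along the strand axis
PLEAT = 0.95             # Å out-of-plane zigzag; gives ~3.8 Å consecutive Cα
INTER_STRAND = 4.8       # Å Cα–Cα separation between paired strands


class ClashSceneError(StructureError):
    pass


@dataclass
class GrooveManifest:
    """Ground truth for a groove complex: component chains and the planted
    typed contacts (epitope atom, partner atom, type, distance)."""

    components: dict[str, str]
    contacts: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# hairpin


def _ca_trace(n_res: int, n_turn: int = 2) -> np.ndarray:
    """Cα positions of an idealized antiparallel two-strand hairpin."""
    n_strand = (n_res - n_turn) // 2
    if 2 * n_strand + n_turn != n_res or n_strand < 2:
        raise StructureError(
            f"cannot split {n_res} residues into two strands plus a {n_turn}-residue turn")
    ca = np.zeros((n_res, 3))
    for i in range(n_strand):
        ca[i] = (i * STRAND_RISE, 0.0, PLEAT * (-1) ** i)
    x_end = (n_strand - 1) * STRAND_RISE
    # turn bulges outward in +x keeping ~3.8 Å steps
    b = 0.5
    a = math.sqrt(3.8 ** 2 - b * b)
    ca[n_strand] = (x_end + a, b, 0.0)
    ca[n_strand + 1] = (x_end + a, INTER_STRAND - b, 0.0)
    for k in range(n_strand):
        i = n_strand + n_turn + k
        ca[i] = (x_end - k * STRAND_RISE, INTER_STRAND, PLEAT * (-1) ** k)
    return ca


def _ring_atoms(res_name: str) -> list[str]:
    rings = {
        "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    }
    return rings[res_name]


def _place_ring(center: np.ndarray, u: np.ndarray, v: np.ndarray,
                names: list[str], radius: float = 1.3) -> list[tuple[str, str, np.ndarray]]:
    out = []
    for k, name in enumerate(names):
        ang = 2.0 * math.pi * k / len(names)
        pos = center + radius * (math.cos(ang) * u + math.sin(ang) * v)
        elem = "N" if name.startswith("N") else "C"
        out.append((name, elem, pos))
    return out


def _sidechain_atoms(res_name: str, ca: np.ndarray, s: np.ndarray,
                     u: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Stylized side chain along direction ``s`` (u = chain direction)."""
    atoms: list[tuple[str, str, np.ndarray]] = []
    if res_name == "GLY":
        return atoms
    cb = ca + 1.3 * s
    atoms.append(("CB", "C", cb))
    if res_name in ("ASP", "GLU"):
        reach = 2.3 if res_name == "ASP" else 3.2
        names = ("OD1", "OD2") if res_name == "ASP" else ("OE1", "OE2")
        carbon = "CG" if res_name == "ASP" else "CD"
        tip = ca + reach * s
        atoms.append((carbon, "C", tip))
        atoms.append((names[0], "O", tip + 1.1 * u))
        atoms.append((names[1], "O", tip - 1.1 * u))
    elif res_name == "LYS":
        atoms.append(("NZ", "N", ca + 3.4 * s))
    elif res_name == "ARG":
        cz = ca + 3.4 * s
        atoms.append(("CZ", "C", cz))
        atoms.append(("NE", "N", cz - 1.1 * u))
        atoms.append(("NH1", "N", cz + 1.1 * u))
        atoms.append(("NH2", "N", cz + 1.1 * s))
    elif res_name in ("PHE", "TYR", "TRP", "HIS"):
        center = ca + 2.8 * s
        w = np.cross(s, u)
        atoms.extend(_place_ring(center, u, w, _ring_atoms(res_name)))
        if res_name == "TYR":
            atoms.append(("OH", "O", center + 2.4 * s))
    elif res_name in ("SER", "THR"):
        atoms.append(("OG" if res_name == "SER" else "OG1", "O", ca + 2.0 * s))
    elif res_name == "MET":
        atoms.append(("SD", "S", ca + 2.6 * s))
    elif res_name == "ASN":
        atoms.append(("OD1", "O", ca + 2.4 * s))
        atoms.append(("ND2", "N", ca + 2.4 * s + 1.1 * u))
    elif res_name == "GLN":
        atoms.append(("OE1", "O", ca + 3.0 * s))
        atoms.append(("NE2", "N", ca + 3.0 * s + 1.1 * u))
    return atoms


def make_hairpin(sequence: str, start_resnum: int = 286, chain_id: str = "P",
                 disulfide_ends: bool = True, n_turn: int = 2,
                 seed: int = 0, jitter_sd: float = 0.0) -> AtomicStructure:
    """Idealized disulfide-closed antiparallel β-hairpin from a sequence.

    Residue ``i`` of strand one pairs residue ``n-1-i`` of strand two across
    a 4.8 Å inter-strand gap; consecutive Cα spacing is ~3.8 Å including the
    two-residue turn.  When ``disulfide_ends`` is set, the first and last
    cysteines of the sequence get SG atoms placed across the strands ~2.05 Å
    apart and the pair is registered in ``structure.disulfides``.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise StructureError(f"unknown residue letters {sorted(bad)}")
    n = len(sequence)
    ca = _ca_trace(n, n_turn)
    rng = np.random.default_rng(seed)
    if jitter_sd > 0:
        ca = ca + rng.normal(0.0, jitter_sd, ca.shape)

    cys_idx = [i for i, c in enumerate(sequence) if c == "C"]
    if disulfide_ends and len(cys_idx) < 2:
        raise StructureError("disulfide_ends requires at least two cysteines")
    ss_pair = (cys_idx[0], cys_idx[-1]) if disulfide_ends and len(cys_idx) >= 2 else None

    residues: list[Residue] = []
    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE[letter]
        u_next = ca[i + 1] - ca[i] if i + 1 < n else ca[i] - ca[i - 1]
        u_prev = ca[i] - ca[i - 1] if i > 0 else u_next
        u_next = u_next / np.linalg.norm(u_next)
        u_prev = u_prev / np.linalg.norm(u_prev)
        # side-chain direction: continue the pleat out of the sheet plane
        zsign = 1.0 if ca[i][2] >= 0 else -1.0
        s = np.array([0.0, 0.0, zsign])
        # carbonyl points away from the partner strand
        if ca[i][1] < INTER_STRAND / 2:
            w = np.array([0.0, -1.0, 0.0])
        else:
            w = np.array([0.0, 1.0, 0.0])

        atoms = [
            Atom("N", "N", ca[i] - 1.46 * u_prev),
            Atom("CA", "C", ca[i]),
            Atom("C", "C", ca[i] + 1.52 * u_next),
            Atom("O", "O", ca[i] + 1.52 * u_next + 1.23 * w),
        ]
        if ss_pair is not None and i in ss_pair:
            j = ss_pair[1] if i == ss_pair[0] else ss_pair[0]
            d = ca[j] - ca[i]
            d = d / np.linalg.norm(d)
            atoms.append(Atom("CB", "C", ca[i] + 0.7 * d + 0.9 * s))
            atoms.append(Atom("SG", "S", ca[i] + (np.linalg.norm(ca[j] - ca[i]) - 2.05) / 2.0 * d))
        else:
            atoms.extend(Atom(nm, el, xyz)
                         for nm, el, xyz in _sidechain_atoms(res_name, ca[i], s, u_next))
        residues.append(Residue(chain_id, start_resnum + i, res_name, "", atoms))

    st = AtomicStructure([Chain(chain_id, residues)],
                         metadata={"accession": "SYNH", "synthetic": True,
                                   "title": "synthetic idealized beta-hairpin"})
    if ss_pair is not None:
        st.disulfides.append((residues[ss_pair[0]].rid, residues[ss_pair[1]].rid))
    st.validate()
    return st


# ---------------------------------------------------------------------------
# groove complex


def _slab_chain(chain_id: str, z_plane: float, xlim: tuple[float, float],
                ylim: tuple[float, float], spacing: float = 3.2,
                start_resnum: int = 500) -> list[Residue]:
    """A rigid grid of carbon pseudo-residues at one z plane."""
    residues = []
    num = start_resnum
    xs = np.arange(xlim[0], xlim[1] + spacing / 2, spacing)
    ys = np.arange(ylim[0], ylim[1] + spacing / 2, spacing)
    for x in xs:
        for y in ys:
            residues.append(Residue(chain_id, num, "GLY", "",
                                    [Atom("CA", "C", np.array([x, y, z_plane]))]))
            num += 1
    return residues


def make_groove_complex(hairpin: AtomicStructure, groove_gap: float = 4.0,
                        seed: int = 0) -> tuple[AtomicStructure, GrooveManifest]:
    """Dock a hairpin between two mock antibody chains.

    Two rigid slabs (chains ``H`` above, ``L`` below the hairpin plane) flank
    the peptide at ``groove_gap`` Å from its extreme atoms, and typed contact
    partners are planted opposite suitable hairpin side chains: a lysine NZ
    3.2 Å from the first acidic carboxylate oxygen (ionic), a tyrosine ring
    with its nearest atom ~3.0 Å from the first hairpin lysine NZ (cation-π),
    and a backbone-style amide N 3.0 Å from a mid-peptide carbonyl O
    (hydrogen bond).  Partner residue numbers (98, 92, 33) fall inside
    conventional CDR windows so CDR attribution is exercised too.
    """
    if groove_gap <= 0:
        raise ValueError("groove_gap must be positive")
    pep_chain = hairpin.chains[0].chain_id
    complex_st = hairpin.copy()
    xyz = complex_st.coords()
    zmax, zmin = xyz[:, 2].max(), xyz[:, 2].min()
    xlim = (xyz[:, 0].min() - 2.0, xyz[:, 0].max() + 2.0)
    ylim = (xyz[:, 1].min() - 2.0, xyz[:, 1].max() + 2.0)

    heavy = Chain("H", _slab_chain("H", zmax + groove_gap, xlim, ylim))
    light = Chain("L", _slab_chain("L", zmin - groove_gap, xlim, ylim))

    manifest = GrooveManifest(components={"peptide": pep_chain,
                                          "heavy": "H", "light": "L"})
    # a wide groove is an open (non-contacting) scene: nothing is planted
    plant = groove_gap <= 6.0

    def side_chain_for(z: float) -> Chain:
        return heavy if z >= (zmax + zmin) / 2 else light

    def record(res_e: Residue, atom_e: Atom, res_p: Residue, atom_p: Atom,
               itype: str) -> None:
        manifest.contacts.append({
            "epitope": (res_e.chain_id, res_e.seq_num, atom_e.name),
            "partner": (res_p.chain_id, res_p.seq_num, atom_p.name),
            "type": itype,
            "distance": round(float(np.linalg.norm(atom_e.coords - atom_p.coords)), 2),
        })

    residues = list(complex_st.residues()) if plant else []

    # ionic: Lys NZ planted 3.2 Å beyond the first acidic tip
    acid = next((r for r in residues if r.res_name in ("ASP", "GLU")
                 and (r.has_atom("OD1") or r.has_atom("OE1"))), None)
    if acid is not None:
        o = acid.get_atom("OD1" if acid.has_atom("OD1") else "OE1")
        zdir = 1.0 if o.coords[2] >= (zmax + zmin) / 2 else -1.0
        nz = Atom("NZ", "N", o.coords + np.array([0.0, 0.0, 3.2 * zdir]))
        target = side_chain_for(o.coords[2])
        res = Residue(target.chain_id, 98, "LYS", "",
                      [Atom("CA", "C", nz.coords + np.array([0.0, 0.0, 2.0 * zdir])), nz])
        target.residues.append(res)
        record(acid, o, res, nz, "ionic")

    # cation-π: Tyr ring planted over the first hairpin lysine NZ
    lys = next((r for r in residues if r.res_name == "LYS" and r.has_atom("NZ")), None)
    if lys is not None:
        nz = lys.get_atom("NZ")
        zdir = 1.0 if nz.coords[2] >= (zmax + zmin) / 2 else -1.0
        center = nz.coords + np.array([0.0, 0.0, 4.2 * zdir])
        ring = _place_ring(center, np.array([1.0, 0.0, 0.0]),
                           np.array([0.0, 0.0, zdir]), _ring_atoms("TYR"))
        # nearest ring atom sits ~3 Å from NZ, inside the cation-π cutoff
        atoms = [Atom("CA", "C", center + np.array([0.0, 0.0, 2.5 * zdir]))]
        atoms += [Atom(nm, el, pos) for nm, el, pos in ring]
        target = side_chain_for(nz.coords[2])
        res = Residue(target.chain_id, 92, "TYR", "", atoms)
        target.residues.append(res)
        nearest = min((a for a in atoms if a.name != "CA"),
                      key=lambda a: np.linalg.norm(a.coords - nz.coords))
        record(lys, nz, res, nearest, "cation_pi")

    # H-bond: amide N planted against a mid-peptide backbone carbonyl O
    if residues:
        mid = residues[len(residues) // 3]
        o = mid.get_atom("O")
        zdir = 1.0 if o.coords[2] >= (zmax + zmin) / 2 else -1.0
        namide = Atom("N", "N", o.coords + np.array([0.0, 0.0, 3.0 * zdir]))
        target = side_chain_for(o.coords[2])
        res = Residue(target.chain_id, 33, "SER", "",
                      [namide, Atom("CA", "C", namide.coords + np.array([0.0, 0.0, 1.8 * zdir]))])
        target.residues.append(res)
        record(mid, o, res, namide, "h_bond")

    for ch in (heavy, light):
        ch.residues.sort(key=lambda r: r.seq_num)
    complex_st.chains.extend([heavy, light])
    complex_st.metadata.update({"accession": "SYNG", "synthetic": True,
                                "title": "synthetic groove complex"})
    complex_st.validate()
    return complex_st, manifest


# ---------------------------------------------------------------------------
# clash scene


def make_clash_scene(n_atoms: int = 400, n_planted_clashes: int = 10,
                     box: float = 60.0, seed: int = 0,
                     overlap_tolerance: float = 0.4,
                     max_retries: int = 200
                     ) -> tuple[AtomicStructure, AtomicStructure, int]:
    """Two carbon-atom structures with an exactly known inter-structure
    clash count.

    Background atoms of structure A are rejection-sampled to stay at least
    0.2 Å clear of any clash with structure B; each planted pair overlaps by
    a clear margin with exactly one partner.  The ground truth is verified by
    an all-pairs scan before the scene is returned.
    """
    r = 1.7  # carbon vdW
    clash_cut = 2 * r - overlap_tolerance
    safe = 2 * r + 0.2
    rng = np.random.default_rng(seed)
    n_b = n_atoms // 2
    n_a = n_atoms - n_b - n_planted_clashes
    if n_a < 0:
        raise ClashSceneError("more planted clashes than atoms available")

    b_xyz = rng.uniform(0.0, box, (n_b, 3))

    from scipy.spatial import cKDTree
    b_tree = cKDTree(b_xyz)

    a_pts: list[np.ndarray] = []
    tries = 0
    while len(a_pts) < n_a:
        p = rng.uniform(0.0, box, 3)
        if not b_tree.query_ball_point(p, safe):
            a_pts.append(p)
        tries += 1
        if tries > max_retries * max(n_a, 1):
            raise ClashSceneError(f"cannot place {n_a} clash-free atoms in a {box} Å box")

    # plant against targets that have elbow room: a target whose nearest
    # neighbour is closer than ~1 Å can leave no clash-isolating direction
    d_plant = clash_cut - 0.3
    nn_dist, _ = b_tree.query(b_xyz, k=2)
    eligible = list(np.where(nn_dist[:, 1] >= 3.0)[0]) if n_b > 1 else [0]
    if len(eligible) < n_planted_clashes:
        raise ClashSceneError(
            f"only {len(eligible)} isolable target atoms for "
            f"{n_planted_clashes} planted clashes; enlarge the box")
    order = rng.permutation(eligible)
    planted = 0
    for j in order:
        if planted == n_planted_clashes:
            break
        for _ in range(max_retries):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = b_xyz[j] + d_plant * v
            if b_tree.query_ball_point(p, safe) == [int(j)]:
                a_pts.append(p)
                planted += 1
                break
    if planted < n_planted_clashes:
        raise ClashSceneError("could not isolate enough planted clash pairs")

    def to_structure(points: list[np.ndarray] | np.ndarray, chain_id: str,
                     title: str) -> AtomicStructure:
        residues = [Residue(chain_id, i + 1, "UNK", "",
                            [Atom("C1", "C", np.asarray(p))])
                    for i, p in enumerate(points)]
        return AtomicStructure([Chain(chain_id, residues)],
                               metadata={"accession": "SYNC", "synthetic": True,
                                         "title": title})

    st_a = to_structure(a_pts, "F", "synthetic clash scene, mobile")
    st_b = to_structure(b_xyz, "R", "synthetic clash scene, target")

    # internal all-pairs verification of the advertised ground truth
    a_arr = np.array(a_pts)
    d = np.linalg.norm(a_arr[:, None, :] - b_xyz[None, :, :], axis=2)
    truth = int(np.sum(d < clash_cut))
    if truth != n_planted_clashes:
        raise ClashSceneError(
            f"generated scene has {truth} clashes, wanted {n_planted_clashes}")
    return st_a, st_b, truth


# ---------------------------------------------------------------------------
# occluded receptor (accessibility scenes)


def make_occluded_receptor(fab_complex: AtomicStructure,
                           peptide_chain: str = "P",
                           n_blockers: int = 0,
                           seed: int = 0,
                           receptor_chain: str = "R",
                           blocker_start: int = 400
                           ) -> tuple[AtomicStructure, np.ndarray, np.ndarray]:
    """A decoy receptor carrying the epitope at a known rigid transform.

    The receptor is a copy of the bound peptide (renumbered to
    ``receptor_chain``, residue numbers kept) moved by a random proper
    rotation + translation, plus ``n_blockers`` carbon atoms placed exactly
    at the transformed positions of evenly spaced Fab atoms.  Grafting the
    Fab back onto this receptor must recover the planted transform, and each
    blocker then overlaps the grafted Fab — so the blocker count dials the
    scene from open (0) through partially to heavily occluded, emulating how
    receptor conformations bury the epitope to different degrees.

    Returns (receptor, rotation, translation).
    """
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    rot = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(rot) < 0:
        rot[:, 0] = -rot[:, 0]
    trans = rng.uniform(-30.0, 30.0, 3)

    peptide = select_region(fab_complex, chain_ids=[peptide_chain])
    residues: list[Residue] = []
    for res in peptide.residues():
        atoms = [Atom(a.name, a.element, rot @ a.coords + trans)
                 for a in res.atoms]
        residues.append(Residue(receptor_chain, res.seq_num, res.res_name,
                                res.icode, atoms))

    fab_atoms = [(r_, a) for r_, a in fab_complex.atoms()
                 if r_.chain_id != peptide_chain]
    if not fab_atoms:
        raise StructureError("fab complex has no non-peptide atoms to occlude")
    if n_blockers > 0:
        # cycle over the Fab atoms when more blockers than atoms are asked
        # for: several blockers on one atom still count as separate clashes
        picks = [k % len(fab_atoms) for k in range(n_blockers)]
        for k, idx in enumerate(picks):
            _, a = fab_atoms[idx]
            residues.append(Residue(receptor_chain, blocker_start + k, "UNK", "",
                                    [Atom("C1", "C", rot @ a.coords + trans)]))

    st = AtomicStructure([Chain(receptor_chain, residues)],
                         metadata={"accession": "SYNR", "synthetic": True,
                                   "title": "synthetic occluded receptor"})
    st.validate()
    return st, rot, trans


# ---------------------------------------------------------------------------
# sensorgrams


def make_sensorgram_set(true_params: KineticParams,
                        concentrations: list[float],
                        noise_sd: float = 0.0, seed: int = 0,
                        t_assoc: float = 600.0, t_dissoc: float = 900.0,
                        dt: float = 5.0) -> tuple[list[Sensorgram], dict]:
    """Simulate one trace per concentration plus a truth manifest."""
    if not concentrations:
        raise ValueError("need at least one concentration")
    rng = np.random.default_rng(seed)
    traces = [simulate_sensorgram(true_params, c, t_assoc, t_dissoc, dt,
                                  noise_sd, rng)
              for c in concentrations]
    manifest = {
        "ka": true_params.ka,
        "kd": true_params.kd,
        "rmax": true_params.rmax,
        "KD_nM": true_params.KD_nM,
        "concentrations_M": list(concentrations),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return traces, manifest
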