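"""Graft-and-clash accessibility modelling on scenes with known ground truth."""

import numpy as np
import pytest

from epifab import (
    DomainMap,
    build_egfrviii_model,
    classify_accessibility,
    count_clashes,
    graft_fab,
    make_clash_scene,
    make_occluded_receptor,
    select_region,
    truncate_n_terminal,
)
from epifab.structures import Atom, AtomicStructure, Chain, Residue
from conftest import random_rotation


def all_pairs_clash_count(a, b, tolerance=0.4, exclude=None, radius=1.7):
    """Brute-force O(n^2) oracle over carbon scenes."""
    ax = a.coords()
    b_atoms = [(r, at) for r, at in b.atoms()
               if exclude is None or not (exclude[0] <= r.seq_num <= exclude[1])]
    bx = np.array([at.coords for _, at in b_atoms])
    d = np.linalg.norm(ax[:, None, :] - bx[None, :, :], axis=2)
    return int(np.sum(d < 2 * radius - tolerance))


def test_domain_map_lookup_and_overlap_rejection():
    dm = DomainMap({"I": (1, 164), "II": (165, 310)})
    assert dm.domain_of(100) == "I"
    assert dm.domain_of(165) == "II"
    assert dm.domain_of(700) == "unmapped"
    with pytest.raises(ValueError):
        DomainMap({"a": (1, 10), "b": (5, 20)})


def test_self_graft_is_identity(groove):
    cx, _ = groove
    receptor = select_region(cx, chain_ids=["P"])  # receptor == the bound peptide
    result = graft_fab(cx, receptor, "P", "P",
                       epitope_range=(287, 302), hairpin_range=(293, 302))
    assert result.alignment_rmsd < 1e-6
    assert np.allclose(result.transform.rotation, np.eye(3), atol=1e-6)
    fab_orig = select_region(cx, chain_ids=["H", "L"])
    assert np.abs(result.fab.coords() - fab_orig.coords()).max() < 1e-6
    assert "P" not in result.fab.chain_ids


def test_graft_recovers_planted_transform(groove):
    cx, _ = groove
    receptor, rot, trans = make_occluded_receptor(cx, "P", n_blockers=0, seed=5)
    result = graft_fab(cx, receptor, "P", "R")
    assert result.alignment_rmsd < 1e-6
    fab_orig = select_region(cx, chain_ids=["H", "L"])
    expected = fab_orig.coords() @ rot.T + trans
    assert np.abs(result.fab.coords() - expected).max() < 1e-6


def test_graft_warns_above_rmsd_ceiling(groove):
    cx, _ = groove
    receptor, _, _ = make_occluded_receptor(cx, "P", seed=5)
    # mangle the receptor epitope so the hairpin cannot align well
    rng = np.random.default_rng(0)
    receptor.set_coords(receptor.coords() + rng.normal(scale=3.0,
                                                       size=(receptor.n_atoms, 3)))
    with pytest.warns(UserWarning, match="rmsd"):
        result = graft_fab(cx, receptor, "P", "R")
    assert result.rmsd_warning


def test_clash_count_matches_planted_and_oracle():
    a, b, truth = make_clash_scene(400, 17, box=60.0, seed=7)
    rep = count_clashes(a, b, overlap_tolerance=0.4)
    assert rep.n_clashes == truth == 17
    assert rep.n_clashes == all_pairs_clash_count(a, b)
    assert sum(rep.per_chain.values()) == rep.n_clashes
    assert sum(rep.per_domain.values()) == rep.n_clashes


def test_zero_planted_means_zero_counted():
    a, b, truth = make_clash_scene(200, 0, box=60.0, seed=3)
    assert truth == 0
    assert count_clashes(a, b).n_clashes == 0


def test_spatial_binning_equals_all_pairs_on_2000_atoms():
    a, b, truth = make_clash_scene(2000, 25, box=100.0, seed=1)
    rep = count_clashes(a, b, overlap_tolerance=0.4)
    assert rep.n_clashes == all_pairs_clash_count(a, b) == truth


def test_clash_count_rigid_invariance():
    a, b, _ = make_clash_scene(300, 9, box=60.0, seed=2)
    n0 = count_clashes(a, b).n_clashes
    rng = np.random.default_rng(4)
    rot, trans = random_rotation(rng), rng.normal(scale=20, size=3)
    for st in (a, b):
        st.set_coords(st.coords() @ rot.T + trans)
    assert count_clashes(a, b).n_clashes == n0


def test_clash_count_monotone_in_tolerance():
    a, b, _ = make_clash_scene(300, 12, box=60.0, seed=6)
    counts = [count_clashes(a, b, overlap_tolerance=tol).n_clashes
              for tol in (0.0, 0.2, 0.4, 0.6, 1.0)]
    assert counts == sorted(counts, reverse=True)


def test_epitope_exclusion_identity(groove):
    """Receptor consisting only of the excluded epitope -> zero clashes."""
    cx, _ = groove
    fab = select_region(cx, chain_ids=["H", "L"])
    peptide = select_region(cx, chain_ids=["P"])
    rep = count_clashes(fab, peptide, exclude_epitope=(286, 303))
    assert rep.n_clashes == 0


def test_disjoint_frames_flagged():
    a, b, _ = make_clash_scene(100, 0, box=40.0, seed=8)
    far = a.copy()
    far.set_coords(a.coords() + 500.0)
    with pytest.warns(UserWarning, match="disjoint"):
        rep = count_clashes(far, b)
    assert rep.frames_disjoint and rep.n_clashes == 0


def test_classify_accessibility_thresholds():
    from epifab.accessibility import ClashReport

    def rep(n):
        return ClashReport(n, {}, {}, 0.0, 0.4, "bondi")

    assert classify_accessibility(rep(0)).label == "accessible"
    assert classify_accessibility(rep(10)).label == "accessible"
    assert classify_accessibility(rep(11)).label == "partial"
    assert classify_accessibility(rep(199)).label == "partial"
    assert classify_accessibility(rep(200)).label == "inaccessible"
    with pytest.raises(ValueError):
        classify_accessibility(rep(0), accessible_max=5, inaccessible_min=5)


def test_truncation_model_keeps_epitope():
    chain = Chain("R", [Residue("R", i, "GLY", "",
                                [Atom("CA", "C", [float(i), 0, 0])])
                        for i in range(1, 619)])
    st = AtomicStructure([chain])
    model = build_egfrviii_model(st, "R", cut_after=273)
    nums = [r.seq_num for r in model.chain("R")]
    assert nums[0] == 274 and nums[-1] == 618
    kept = select_region(model, chain_ids=["R"], residue_range=(287, 302))
    assert kept.n_residues == 16


def test_three_scenario_clash_ordering(groove):
    """Open / partially occluded / heavily occluded receptor conformations
    produce strictly ordered clash counts and the three expected calls."""
    cx, _ = groove
    dm = DomainMap({"II": (165, 310), "III": (311, 480), "IV": (481, 618)})
    counts = {}
    calls = {}
    for name, blockers in (("untethered_like", 300),
                           ("tethered_like", 40),
                           ("truncated", 0)):
        receptor, _, _ = make_occluded_receptor(cx, "P", n_blockers=blockers,
                                                seed=9)
        result = graft_fab(cx, receptor, "P", "R")
        rep = count_clashes(result.fab, receptor, exclude_epitope=(286, 303),
                            domain_map=dm)
        counts[name] = rep.n_clashes
        calls[name] = classify_accessibility(rep).label
        assert rep.n_clashes >= blockers  # every blocker overlaps the Fab
    assert counts["untethered_like"] > counts["tethered_like"] > counts["truncated"] == 0
    assert calls == {"untethered_like": "inaccessible",
                     "tethered_like": "partial",
                     "truncated": "accessible"}


def test_truncating_occluders_removes_clashes(groove):
    """Cutting the blocker-bearing segment of the receptor chain mimics the
    deletion variant: the same graft then lands clash-free."""
    cx, _ = groove
    receptor, _, _ = make_occluded_receptor(cx, "P", n_blockers=60, seed=12,
                                            blocker_start=150)  # blockers 150-209
    blocked = graft_fab(cx, receptor, "P", "R")
    n_blocked = count_clashes(blocked.fab, receptor,
                              exclude_epitope=(286, 303)).n_clashes
    assert n_blocked >= 60
    cleared = truncate_n_terminal(receptor, "R", 273)  # drops all blockers
    regraft = graft_fab(cx, cleared, "P", "R")
    n_clear = count_clashes(regraft.fab, cleared,
                            exclude_epitope=(286, 303)).n_clashes
    assert n_clear == 0 < n_blocked
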