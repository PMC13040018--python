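"""Typed contact detection against constructed geometry and a brute-force
all-pairs oracle."""

import numpy as np
import pytest

from epifab.contacts import (
    AROMATIC_RING,
    CARBOXYLATE_O,
    CATIONIC_N,
    CdrMap,
    ContactCutoffs,
    classify_contacts,
    classify_pair,
    interface_table,
    measure_distance,
)
from epifab.structures import (
    Atom,
    AtomicStructure,
    AtomNotFoundError,
    Chain,
    Residue,
    StructureError,
    select_region,
)


def pair_structure(res_a, res_b):
    return AtomicStructure([Chain(res_a.chain_id, [res_a]),
                            Chain(res_b.chain_id, [res_b])])


def asp(chain, num, origin, spread=2.2):
    o = np.asarray(origin, float)
    return Residue(chain, num, "ASP", "", [
        Atom("CB", "C", o + [0, 0, -1.5]),
        Atom("OD1", "O", o),
        Atom("OD2", "O", o + [spread, 0, 0]),
    ])


def lys(chain, num, nz):
    return Residue(chain, num, "LYS", "", [Atom("NZ", "N", nz)])


def test_measure_distance(hairpin):
    assert measure_distance(hairpin, ("P", 290, "CA"), ("P", 290, "CA")) == 0.0
    d = measure_distance(hairpin, ("P", 290, "CA"), ("P", 291, "CA"))
    assert 3.6 < d < 4.0
    with pytest.raises(AtomNotFoundError):
        measure_distance(hairpin, ("P", 290, "XX"), ("P", 291, "CA"))


def test_constructed_ionic_pair_at_3_2A():
    st = pair_structure(asp("P", 297, [0, 0, 0]), lys("H", 98, [0, 0, 3.2]))
    recs = classify_contacts(st, select_region(st, chain_ids=["P"]),
                             {"heavy": select_region(st, chain_ids=["H"])})
    ionic = [r for r in recs if r.interaction_type == "ionic"]
    assert len(ionic) >= 1
    best = min(ionic, key=lambda r: r.distance)
    assert best.distance == pytest.approx(3.20, abs=0.005)
    assert best.epitope_atom == "OD1" and best.partner_atom == "NZ"


def test_far_pair_yields_no_records():
    st = pair_structure(asp("P", 297, [0, 0, 0]), lys("H", 98, [0, 0, 10.0]))
    recs = classify_contacts(st, select_region(st, chain_ids=["P"]),
                             {"heavy": select_region(st, chain_ids=["H"])})
    assert recs == []


def test_ionic_precedence_over_h_bond():
    # carboxylate O vs NZ at 3.2 A satisfies both the polar-polar and the
    # salt-bridge rule; it must be reported once, as ionic
    st = pair_structure(asp("P", 297, [0, 0, 0]), lys("H", 98, [0, 0, 3.2]))
    recs = classify_contacts(st, select_region(st, chain_ids=["P"]),
                             {"heavy": select_region(st, chain_ids=["H"])})
    od1 = [r for r in recs if r.epitope_atom == "OD1"]
    assert len(od1) == 1 and od1[0].interaction_type == "ionic"


def test_cation_pi_detection_and_mainchain_flags():
    ring = Residue("L", 92, "TYR", "", [
        Atom(name, "C", np.array([1.3 * np.cos(k), 1.3 * np.sin(k), 0.0]))
        for name, k in zip(["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
                           np.linspace(0, 2 * np.pi, 6, endpoint=False))
    ])
    cat = Residue("P", 300, "ARG", "", [
        Atom("N", "N", [0, 0, 8.0]),            # backbone, far
        Atom("NH1", "N", [0, 0, 3.5]),
    ])
    st = pair_structure(cat, ring)
    recs = classify_contacts(st, select_region(st, chain_ids=["P"]),
                             {"light": select_region(st, chain_ids=["L"])})
    assert recs and all(r.interaction_type == "cation_pi" for r in recs)
    assert all(r.epitope_atom == "NH1" and not r.epitope_mainchain for r in recs)


def test_cdr_attribution_from_configured_ranges(cdr_map):
    st = pair_structure(asp("P", 295, [0, 0, 0]), lys("H", 98, [0, 0, 3.2]))
    recs = classify_contacts(st, select_region(st, chain_ids=["P"]),
                             {"heavy": select_region(st, chain_ids=["H"])},
                             cdr_map)
    assert all(r.cdr == "H3" for r in recs)
    off = pair_structure(asp("P", 295, [0, 0, 0]), lys("H", 120, [0, 0, 3.2]))
    recs_off = classify_contacts(off, select_region(off, chain_ids=["P"]),
                                 {"heavy": select_region(off, chain_ids=["H"])},
                                 cdr_map)
    assert all(r.cdr is None for r in recs_off)


def test_overlapping_cdr_ranges_rejected():
    with pytest.raises(ValueError):
        CdrMap({"heavy": [("H1", (26, 35)), ("H2", (30, 40))]})


def test_raising_cutoff_never_removes_records(groove, cdr_map):
    cx, _ = groove
    ep = select_region(cx, chain_ids=["P"])
    groups = {"heavy": select_region(cx, chain_ids=["H"]),
              "light": select_region(cx, chain_ids=["L"])}

    def keys(cutoffs):
        return {(r.epitope_seq_num, r.epitope_atom, r.partner_seq_num,
                 r.partner_atom, r.interaction_type)
                for r in classify_contacts(cx, ep, groups, cdr_map, cutoffs)}

    base = ContactCutoffs()
    wide = ContactCutoffs(h_bond=3.9, ionic=4.4, cation_pi=5.0)
    base_keys, wide_keys = keys(base), keys(wide)
    assert {k for k in base_keys if k[-1] == "h_bond"} <= \
           {k for k in wide_keys if k[-1] == "h_bond"}
    assert {k for k in base_keys if k[-1] == "cation_pi"} <= \
           {k for k in wide_keys if k[-1] == "cation_pi"}


def brute_force_contacts(epitope_atoms, partner_atoms, cutoffs):
    """All-pairs re-application of the published rules, order-free."""
    out = set()
    for res_e, atom_e in epitope_atoms:
        for res_p, atom_p in partner_atoms:
            d = float(np.linalg.norm(atom_e.coords - atom_p.coords))
            t = classify_pair(res_e, atom_e, res_p, atom_p, d, cutoffs)
            if t is not None:
                out.add((res_e.seq_num, atom_e.name, res_p.seq_num,
                         atom_p.name, t, round(d, 2)))
    return out


def test_brute_force_oracle_on_groove_scene(groove, cdr_map):
    cx, manifest = groove
    assert cx.n_atoms <= 500
    cutoffs = ContactCutoffs()
    ep = select_region(cx, chain_ids=["P"])
    groups = {"heavy": select_region(cx, chain_ids=["H"]),
              "light": select_region(cx, chain_ids=["L"])}
    recs = classify_contacts(cx, ep, groups, cdr_map, cutoffs)
    got = {(r.epitope_seq_num, r.epitope_atom, r.partner_seq_num,
            r.partner_atom, r.interaction_type, r.distance) for r in recs}
    expected = set()
    for role in ("H", "L"):
        expected |= brute_force_contacts(
            list(ep.atoms()),
            list(select_region(cx, chain_ids=[role]).atoms()), cutoffs)
    assert got == expected


def test_manifest_contacts_all_recovered(groove, cdr_map):
    cx, manifest = groove
    ep = select_region(cx, chain_ids=["P"])
    groups = {"heavy": select_region(cx, chain_ids=["H"]),
              "light": select_region(cx, chain_ids=["L"])}
    recs = classify_contacts(cx, ep, groups, cdr_map)
    got = {((r.epitope_seq_num, r.epitope_atom),
            (r.partner_seq_num, r.partner_atom), r.interaction_type)
           for r in recs}
    for c in manifest.contacts:
        key = ((c["epitope"][1], c["epitope"][2]),
               (c["partner"][1], c["partner"][2]), c["type"])
        assert key in got, f"planted contact not recovered: {c}"


def test_distances_consistent_with_measure_distance(groove):
    cx, _ = groove
    ep = select_region(cx, chain_ids=["P"])
    groups = {"heavy": select_region(cx, chain_ids=["H"]),
              "light": select_region(cx, chain_ids=["L"])}
    for r in classify_contacts(cx, ep, groups):
        chain = "H" if r.partner_chain_role == "heavy" else "L"
        d = measure_distance(cx, ("P", r.epitope_seq_num, r.epitope_atom),
                             (chain, r.partner_seq_num, r.partner_atom))
        assert r.distance == pytest.approx(d, abs=0.005)


def test_interface_table_rendering():
    st = pair_structure(asp("P", 297, [0, 0, 0]), lys("H", 98, [0, 0, 3.2]))
    recs = classify_contacts(st, select_region(st, chain_ids=["P"]),
                             {"heavy": select_region(st, chain_ids=["H"])})
    tsv = interface_table(recs)
    lines = tsv.strip().split("\n")
    assert lines[0].startswith("epitope\t")
    assert any("ionic" in ln for ln in lines[1:])
    assert interface_table([]).strip().split("\n") == [lines[0]]
    # backbone atoms are starred
    o_res = Residue("P", 298, "GLY", "", [Atom("O", "O", [0, 0, 0])])
    n_res = Residue("H", 103, "GLY", "", [Atom("N", "N", [0, 0, 3.0])])
    st2 = pair_structure(o_res, n_res)
    recs2 = classify_contacts(st2, select_region(st2, chain_ids=["P"]),
                              {"heavy": select_region(st2, chain_ids=["H"])})
    assert "G298 (O*)" in interface_table(recs2)
    assert "G103 (N*)" in interface_table(recs2)


def test_empty_epitope_group_rejected(groove):
    cx, _ = groove
    empty = select_region(cx, chain_ids=["P"], residue_range=(900, 901))
    with pytest.raises(StructureError):
        classify_contacts(cx, empty, {"heavy": select_region(cx, chain_ids=["H"])})
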