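"""Contact detection at the 4 Å cutoff and the relational store."""

import numpy as np
import pytest

from templex import fixtures as fx
from templex.assembly import AsmblMol, build_assembly
from templex.contacts import (
    SelfContactError,
    build_contact_table,
    build_database,
    find_contact_residues,
)
from templex.mmcif_model import Atom, parse_entry


def _mol(asym, oper, coords, seq_ids=None, element="C"):
    seq_ids = seq_ids or [None] * len(coords)
    atoms = [Atom(f"{element}{i}", element, "LIG", s, np.array(c, dtype=float))
             for i, (c, s) in enumerate(zip(coords, seq_ids))]
    return AsmblMol("9zzz", asym, oper, atoms)


def test_cutoff_boundary():
    a = _mol("A", "1", [[0, 0, 0]])
    near = _mol("B", "1", [[3.9, 0, 0]])
    far = _mol("C", "1", [[4.1, 0, 0]])
    c = find_contact_residues(a, near)
    assert c is not None and c.seq_ids_a == [1] and c.seq_ids_b == [1]
    assert find_contact_residues(a, far) is None


def test_hydrogens_are_ignored():
    a = _mol("A", "1", [[0, 0, 0]])
    b = AsmblMol("9zzz", "B", "1", [
        Atom("H1", "H", "LIG", None, np.array([2.0, 0, 0])),
        Atom("C1", "C", "LIG", None, np.array([9.0, 0, 0])),
    ])
    assert find_contact_residues(a, b) is None


def test_self_contact_rejected():
    a = _mol("A", "1", [[0, 0, 0]])
    with pytest.raises(SelfContactError):
        find_contact_residues(a, a)


def _brute_force(a, b, cutoff=4.0):
    res_a, res_b = set(), set()
    for at in a.atoms:
        if not at.is_heavy:
            continue
        for bt in b.atoms:
            if not bt.is_heavy:
                continue
            if np.linalg.norm(at.xyz - bt.xyz) <= cutoff:
                res_a.add(at.seq_id or 1)
                res_b.add(bt.seq_id or 1)
    return sorted(res_a), sorted(res_b)


def test_grid_search_equals_all_pairs_scan_on_random_molecules():
    rng = np.random.default_rng(5)
    for trial in range(50):
        na, nb = rng.integers(5, 40, size=2)
        a = _mol("A", "1", rng.uniform(0, 15, size=(na, 3)),
                 seq_ids=list(rng.integers(1, 10, size=na)))
        b = _mol("B", "1", rng.uniform(3, 18, size=(nb, 3)),
                 seq_ids=list(rng.integers(1, 10, size=nb)))
        exp_a, exp_b = _brute_force(a, b)
        got = find_contact_residues(a, b)
        if not exp_a:
            assert got is None
        else:
            assert (got.seq_ids_a, got.seq_ids_b) == (exp_a, exp_b)


def test_contact_symmetry_and_cutoff_monotonicity():
    rng = np.random.default_rng(9)
    a = _mol("A", "1", rng.uniform(0, 12, size=(25, 3)),
             seq_ids=list(rng.integers(1, 8, size=25)))
    b = _mol("B", "1", rng.uniform(2, 14, size=(25, 3)),
             seq_ids=list(rng.integers(1, 8, size=25)))
    fwd = find_contact_residues(a, b)
    rev = find_contact_residues(b, a)
    assert (fwd is None) == (rev is None)
    if fwd is not None:
        assert fwd.seq_ids_a == rev.seq_ids_b and fwd.seq_ids_b == rev.seq_ids_a
    sets = {}
    for cutoff in (3.5, 4.0, 4.5):
        c = find_contact_residues(a, b, cutoff)
        sets[cutoff] = (set(), set()) if c is None else \
            (set(c.seq_ids_a), set(c.seq_ids_b))
    assert sets[3.5][0] <= sets[4.0][0] <= sets[4.5][0]
    assert sets[3.5][1] <= sets[4.0][1] <= sets[4.5][1]


def test_contact_table_pair_counting():
    tri = [_mol("A", "1", [[0, 0, 0]]), _mol("B", "1", [[3, 0, 0]]),
           _mol("C", "1", [[1.5, 2.5, 0]])]
    assert len(build_contact_table(tri, "1")) == 3
    dimers = [_mol("A", "1", [[0, 0, 0]]), _mol("B", "1", [[3, 0, 0]]),
              _mol("C", "1", [[100, 0, 0]]), _mol("D", "1", [[103, 0, 0]])]
    pairs = {(c.mol_a[0], c.mol_b[0]) for c in build_contact_table(dimers, "1")}
    assert pairs == {("A", "B"), ("C", "D")}


def test_contact_sets_match_ground_truth(demo_entries):
    for entry, truth in demo_entries:
        for aid, info in truth["assemblies"].items():
            got = {}
            for c in build_contact_table(build_assembly(entry, aid), aid):
                if c.mol_b < c.mol_a:
                    c = c.flipped()
                got[(c.mol_a, c.mol_b)] = (c.seq_ids_a, c.seq_ids_b)
            expected = {
                (tuple(x["mol_a"]), tuple(x["mol_b"])): (x["seq_ids_a"], x["seq_ids_b"])
                for x in info["contacts"]}
            assert got == expected


def test_store_query_contacts_homodimer():
    spec = fx.FixtureSpec(
        pdb_id="9dim",
        chains=[fx.ChainSpec("A", 8)],
        operators=[fx.OperSpec("1"), fx.OperSpec("2", translation=(0, 3.6, 0))],
        assemblies=[fx.AssemblySpec("1", [(("A",), "1,2")])],
    )
    store, _ = build_database([parse_entry(fx.make_entry(spec)[0])], cluster=False)
    partners = store.query_contacts("9dim", "A")
    assert len(partners) == 1
    meta, contact = partners[0]
    assert meta.asym_id == "A"  # same unitmol ...
    assert contact.mol_a[1] != contact.mol_b[1]  # ... different operator
    store.close()


def test_store_round_trip_and_scan_oracle(demo_store, demo_entries):
    all_contacts = demo_store.all_contacts()
    for entry, _ in demo_entries:
        for u in entry.unitmols:
            got = demo_store.query_contacts(u.pdb_id, u.asym_id)
            direct = [c for c in all_contacts if c.pdb_id == u.pdb_id and
                      (c.mol_a[0] == u.asym_id or c.mol_b[0] == u.asym_id)]
            assert len(got) == len(direct)
    with pytest.raises(KeyError):
        demo_store.query_contacts("0xxx", "A")


def test_duplicate_pair_across_assemblies_accumulates_ids():
    spec = fx.FixtureSpec(
        pdb_id="9two",
        chains=[fx.ChainSpec("A", 6)],
        hets=[fx.HetSpec("B", "LIG", ("C",), near=("A", 3, 3.0))],
        operators=[fx.OperSpec("1")],
        assemblies=[fx.AssemblySpec("1", [(("A", "B"), "1")]),
                    fx.AssemblySpec("2", [(("A", "B"), "1")])],
    )
    store, _ = build_database([parse_entry(fx.make_entry(spec)[0])], cluster=False)
    (contact,) = store.all_contacts()
    assert contact.assembly_ids == ["1", "2"]
    store.close()
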