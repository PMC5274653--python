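"""Contact prediction services, interaction classes and redundancy rules."""

import pytest

from templex import fixtures as fx
from templex.chem import compound_from_unitmol
from templex.contacts import build_database
from templex.mmcif_model import UnitMol, parse_entry
from templex.predict import (
    PredictionRecord,
    binding_site_tanimoto,
    build_site_table,
    classify_interaction,
    cluster_representatives,
    contact_type_key,
    find_multimer_templates,
    predict_contacts_for_protein,
    predict_proteins_for_compound,
    select_monomer_representatives,
)
from templex.seqsearch import Alignment, search_homologs, SeqDB


@pytest.fixture(scope="module")
def ligand_metal_store():
    """One chain contacting a small compound and a metal."""
    spec = fx.FixtureSpec(
        pdb_id="9plm",
        chains=[fx.ChainSpec("A", 14)],
        hets=[fx.HetSpec("B", "ATP", ("C", "N", "O"), near=("A", 4, 3.4)),
              fx.HetSpec("C", "ZN", ("ZN",), near=("A", 10, 2.3))],
        seed=21,
    )
    store, _ = build_database([parse_entry(fx.make_entry(spec)[0])])
    yield store, spec
    store.close()


@pytest.fixture(scope="module")
def dimer_stores():
    """A homodimer entry and a heterodimer entry in one database."""
    homo = fx.FixtureSpec(
        pdb_id="9hom",
        chains=[fx.ChainSpec("A", 12)],
        operators=[fx.OperSpec("1"), fx.OperSpec("2", translation=(0, 3.6, 0))],
        assemblies=[fx.AssemblySpec("1", [(("A",), "1,2")])],
        seed=31,
    )
    het = fx.FixtureSpec(
        pdb_id="9het",
        chains=[fx.ChainSpec("A", 12), fx.ChainSpec("B", 16, origin=(0, 3.6, 0))],
        seed=32,
    )
    entries = [parse_entry(fx.make_entry(s)[0]) for s in (homo, het)]
    store, _ = build_database(entries)
    yield store, entries
    store.close()


def test_protein_query_finds_ligand_and_metal(ligand_metal_store):
    store, _spec = ligand_metal_store
    query = store.entries["9plm"].unitmol("A").sequence
    records = predict_contacts_for_protein(query, store, backend="internal")
    assert len(records) == 2
    assert {r.interaction_class for r in records} == {"compound", "metal"}
    by_class = {r.interaction_class: r for r in records}
    assert by_class["compound"].contact_type_key == "ATP"
    assert by_class["metal"].contact_type_key == "ZN"
    # identity-100 homolog: contact sites map onto the template residues
    assert by_class["compound"].contact_sites_on_query == [4]
    assert by_class["metal"].contact_sites_on_query == [10]
    for r in records:
        assert r.aln.identity_contact == 100.0
        assert r.mappable


def test_homodimer_and_heterodimer_classes(dimer_stores):
    store, entries = dimer_stores
    homo_seq = entries[0].unitmol("A").sequence
    records = predict_contacts_for_protein(homo_seq, store, backend="internal")
    homo_recs = [r for r in records if r.template_assembly[0] == "9hom"]
    assert homo_recs and all(r.interaction_class == "homo_oligomer" for r in homo_recs)
    het_seq = entries[1].unitmol("A").sequence
    records_b = predict_contacts_for_protein(het_seq, store, backend="internal")
    het_recs = [r for r in records_b if r.template_assembly[0] == "9het"]
    assert het_recs and all(r.interaction_class == "hetero_oligomer" for r in het_recs)


def test_record_count_equals_join_oracle(demo_store):
    query = demo_store.entries["9x00"].unitmol("A").sequence
    records = predict_contacts_for_protein(query, demo_store, backend="internal")
    alns = search_homologs(query, SeqDB(demo_store.protein_sequences()),
                           backend="internal")
    expected = sum(len(demo_store.query_contacts(*a.template_id)) for a in alns)
    assert len(records) == expected
    for rec in records:
        homolog = demo_store.unitmol_meta(rec.template_assembly[0],
                                          rec.homolog_mol[0])
        assert rec.interaction_class == classify_interaction(homolog,
                                                             rec.contact_meta)


def _meta(mol_type, comp_id=None, sequence=None, cluster=None, descr=""):
    return UnitMol("1abc", "Z", mol_type, comp_id, sequence, descr, [],
                   cluster95=cluster)


def test_classify_interaction_rules():
    me = _meta("protein", cluster="c1")
    assert classify_interaction(me, _meta("protein", cluster="c1")) == "homo_oligomer"
    assert classify_interaction(me, _meta("protein", cluster="c2")) == "hetero_oligomer"
    assert classify_interaction(me, _meta("nucleotide", sequence="ACGT")) == "nucleotide"
    assert classify_interaction(me, _meta("compound", comp_id="ATP")) == "compound"
    assert classify_interaction(me, _meta("metal", comp_id="ZN")) == "metal"
    assert classify_interaction(me, _meta("precipitant", comp_id="GOL")) == "precipitant"
    assert classify_interaction(me, _meta("other", descr="glycan")) == "other_polymer"


def test_contact_type_key_rule():
    assert contact_type_key(_meta("protein", cluster="c0042")) == "c0042"
    assert contact_type_key(_meta("compound", comp_id="ATP")) == "ATP"
    assert contact_type_key(_meta("metal", comp_id="ZN")) == "ZN"
    assert contact_type_key(_meta("nucleotide", sequence="ACGTACGT")) == "ACGTACGT"
    assert contact_type_key(_meta("other", descr="polysaccharide")) == "polysaccharide"


def test_binding_site_tanimoto_values():
    assert binding_site_tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0
    assert binding_site_tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5
    assert binding_site_tanimoto({1, 2}, {5, 6}) == 0.0
    assert binding_site_tanimoto(set(), set()) == 0.0


def _rec(type_key, sites, evalue=1e-10, ident_contact=50.0,
         cls="compound", template=("1abc", "A")):
    n = 30
    aln = Alignment("q", template, [(i, i) for i in range(1, n + 1)], 80.0,
                    evalue, 90.0, 100.0, 100.0, "A" * n, "A" * n,
                    identity_contact=ident_contact)
    meta = _meta("compound", comp_id=type_key)
    return PredictionRecord("q", ("1abc", "1"), ("A", "1"), ("Z", "1"), meta,
                            aln, cls, sorted(sites), type_key)


def test_cluster_representatives_truth_table():
    base = {1, 2, 3, 4, 5}
    overlapping = {3, 4, 5, 6, 7}        # Tanimoto 3/7 > 0.2
    disjoint = {20, 21, 22, 23, 24}      # Tanimoto 0

    # same type + overlapping sites -> one cluster
    assert len(cluster_representatives([_rec("ATP", base),
                                        _rec("ATP", overlapping)])) == 1
    # same type + low site Tanimoto -> two clusters
    assert len(cluster_representatives([_rec("ATP", base),
                                        _rec("ATP", disjoint)])) == 2
    # different type + overlapping sites -> two clusters
    assert len(cluster_representatives([_rec("ATP", base),
                                        _rec("GTP", overlapping)])) == 2
    # different type + low Tanimoto -> two clusters
    assert len(cluster_representatives([_rec("ATP", base),
                                        _rec("GTP", disjoint)])) == 2
    # boundary: Tanimoto exactly 0.2 does not link ("more than 0.2")
    a, b = {1, 2, 3}, {3, 10, 11}  # 1/5 = 0.2
    assert len(cluster_representatives([_rec("ATP", a), _rec("ATP", b)])) == 2


def test_cluster_representative_selection_and_partition():
    r_fast = _rec("ATP", {1, 2, 3}, evalue=1e-20, ident_contact=40.0)
    r_slow = _rec("ATP", {2, 3, 4}, evalue=1e-5, ident_contact=90.0)
    clusters = cluster_representatives([r_slow, r_fast])
    assert len(clusters) == 1
    members, rep = clusters[0]
    assert rep is r_fast  # lowest E-value wins
    assert len(members) == 2
    # tie on E-value: higher contact-site identity wins
    tie_lo = _rec("GTP", {1, 2, 3}, evalue=1e-8, ident_contact=10.0)
    tie_hi = _rec("GTP", {2, 3, 4}, evalue=1e-8, ident_contact=80.0)
    (_, rep2), = cluster_representatives([tie_lo, tie_hi])
    assert rep2 is tie_hi
    # raising the threshold never merges more
    lax = cluster_representatives([r_slow, r_fast], site_tanimoto_min=0.1)
    strict = cluster_representatives([r_slow, r_fast], site_tanimoto_min=0.9)
    assert len(strict) >= len(lax)


def _mono_aln(start, end, evalue):
    n = 100
    seq = "A" * n
    pairs = [(i, i) for i in range(start, end + 1)]
    return Alignment("q", (f"1t{start:02d}", "A"), pairs, 50.0, evalue,
                     100.0, 0.0, 0.0, seq, seq)


def test_monomer_selection_boundary_at_exactly_ten_new_residues():
    first = _mono_aln(1, 50, 1e-30)
    adds_10 = _mono_aln(41, 60, 1e-20)   # 10 new positions: dropped
    adds_11 = _mono_aln(41, 61, 1e-10)   # 11 new positions: kept
    kept = select_monomer_representatives([first, adds_10])
    assert kept == [first]
    kept = select_monomer_representatives([first, adds_11])
    assert kept == [first, adds_11]
    subset = _mono_aln(5, 40, 1e-5)
    assert select_monomer_representatives([first, subset]) == [first]


def test_site_table_double_counting_identity(ligand_metal_store):
    store, _spec = ligand_metal_store
    query = store.entries["9plm"].unitmol("A").sequence
    records = predict_contacts_for_protein(query, store, backend="internal")
    table = build_site_table(query, records)
    assert len(table) == len(query)
    total = sum(sum(r.contacting_molecule_types.values()) for r in table)
    assert total == sum(len(r.contact_sites_on_query) for r in records)
    untouched = [r for r in table if not r.contacting_molecule_types]
    assert untouched  # most positions contact nothing
    assert all(r.best_template is not None for r in table)  # full-coverage hit


def test_compound_query_joins_contact_table(ligand_metal_store):
    store, _spec = ligand_metal_store
    atp = store.entries["9plm"].unitmol("B")
    compound_db = {"ATP": compound_from_unitmol(atp)}
    preds = predict_proteins_for_compound(compound_db["ATP"], store, compound_db,
                                          tanimoto_min=0.7)
    assert len(preds) == 1
    assert preds[0].comp_id == "ATP" and preds[0].tanimoto == 1.0
    assert [m.asym_id for m, _c in preds[0].proteins] == ["A"]
    # threshold above every similarity -> nothing
    assert predict_proteins_for_compound(compound_db["ATP"], store, compound_db,
                                         tanimoto_min=1.01) == []


def test_multimer_templates_homo_and_hetero(dimer_stores):
    store, entries = dimer_stores
    homo_seq = entries[0].unitmol("A").sequence
    homo_hits = find_multimer_templates(homo_seq, None, store, backend="internal")
    assert [t.pdb_id for t in homo_hits] == ["9hom"]
    t = homo_hits[0]
    assert t.contact.mol_a[0] == t.contact.mol_b[0] == "A"
    assert t.contact.mol_a[1] != t.contact.mol_b[1]

    seq_a = entries[1].unitmol("A").sequence
    seq_b = entries[1].unitmol("B").sequence
    het_hits = find_multimer_templates(seq_a, seq_b, store, backend="internal")
    assert {t.pdb_id for t in het_hits} == {"9het"}
    # hetero mode refuses same-cluster95 template pairs
    none = find_multimer_templates(homo_seq, homo_seq, store, backend="internal")
    assert none == []


def test_template_count_equals_double_join_oracle(dimer_stores):
    store, entries = dimer_stores
    seq_a = entries[1].unitmol("A").sequence
    seq_b = entries[1].unitmol("B").sequence
    hits = find_multimer_templates(seq_a, seq_b, store, backend="internal")
    db = SeqDB(store.protein_sequences())
    ids_a = {a.template_id for a in search_homologs(seq_a, db, backend="internal")}
    ids_b = {b.template_id for b in search_homologs(seq_b, db, backend="internal")}
    expected = 0
    for c in store.all_contacts():
        for mol_x, mol_y in ((c.mol_a, c.mol_b), (c.mol_b, c.mol_a)):
            xa = (c.pdb_id, mol_x[0])
            yb = (c.pdb_id, mol_y[0])
            if xa in ids_a and yb in ids_b:
                ma = store.unitmol_meta(*xa)
                mb = store.unitmol_meta(*yb)
                if ma.mol_type == mb.mol_type == "protein" and \
                        ma.cluster95 != mb.cluster95:
                    expected += 1
    assert len(hits) == expected
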