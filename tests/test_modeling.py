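"""Kabsch superposition, model generation and script emission."""

import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from templex.assembly import build_assembly
from templex.chem import CompoundGraph, max_common_substructure
from templex.mmcif_model import Atom
from templex.modeling import (
    DegenerateFitError,
    UndockableChainError,
    emit_modeller_script,
    expand_to_biological_unit,
    kabsch_superpose,
    place_compound_rigid,
    sequence_replace,
    template_based_dock,
)
from templex.seqsearch import Alignment


def _quaternion_rmsd(moving, fixed):
    """Independent optimal-superposition rmsd via Horn's quaternion method."""
    m = moving - moving.mean(axis=0)
    f = fixed - fixed.mean(axis=0)
    r = m.T @ f
    k = np.array([
        [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
        [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[2, 0] + r[0, 2]],
        [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], r[1, 1] - r[0, 0] - r[2, 2], r[1, 2] + r[2, 1]],
        [r[0, 1] - r[1, 0], r[2, 0] + r[0, 2], r[1, 2] + r[2, 1], r[2, 2] - r[0, 0] - r[1, 1]],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = max(((m ** 2).sum() + (f ** 2).sum() - 2.0 * lam) / len(m), 0.0)
    return np.sqrt(sq)


def test_kabsch_identity_and_translation():
    pts = np.random.default_rng(0).normal(size=(15, 3))
    rot, trans, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(rot, np.eye(3), atol=1e-9)
    shift = np.array([1.0, -2.0, 0.5])
    rot, trans, rmsd = kabsch_superpose(pts, pts + shift)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(trans, shift, atol=1e-9)


def test_kabsch_agrees_with_quaternion_oracle():
    rng = np.random.default_rng(1)
    for k in range(100):
        n = int(rng.integers(4, 30))
        moving = rng.normal(size=(n, 3)) * 5
        rot = Rotation.random(random_state=k).as_matrix()
        fixed = moving @ rot.T + rng.normal(size=3) + rng.normal(size=(n, 3)) * 0.1
        _r, _t, rmsd = kabsch_superpose(moving, fixed)
        assert rmsd == pytest.approx(_quaternion_rmsd(moving, fixed), abs=1e-6)


def test_kabsch_rmsd_invariant_under_rigid_pretransform():
    rng = np.random.default_rng(2)
    moving = rng.normal(size=(12, 3))
    fixed = moving + rng.normal(size=(12, 3)) * 0.3
    base = kabsch_superpose(moving, fixed)[2]
    pre = Rotation.random(random_state=9).as_matrix()
    shift = np.array([3.0, -1.0, 7.0])
    again = kabsch_superpose(moving @ pre.T + shift, fixed @ pre.T + shift)[2]
    assert again == pytest.approx(base, abs=1e-9)


def test_kabsch_degenerate_inputs():
    with pytest.raises(DegenerateFitError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(DegenerateFitError):
        kabsch_superpose(line, line)


def _identity_aln(seq, template_seq=None):
    t = template_seq or seq
    n = min(len(seq), len(t))
    return Alignment("q", ("9zzz", "A"), [(i, i) for i in range(1, n + 1)],
                     100.0, 1e-30, 100.0, 100.0, 100.0, seq, t)


@pytest.fixture()
def template_chain(simple_entry):
    entry, _ = simple_entry
    return build_assembly(entry, "1")[0], entry


def test_sequence_replace_moves_no_atom_and_renames(template_chain):
    tmpl, entry = template_chain
    tseq = entry.unitmol("A").sequence
    qseq = tseq[:3] + ("V" if tseq[3] != "V" else "W") + tseq[4:]
    chain = sequence_replace(tmpl, _identity_aln(qseq, tseq), qseq)
    assert len(chain.atoms) == len(tmpl.atoms)
    disp = max(np.linalg.norm(a.xyz - b.xyz)
               for a, b in zip(chain.atoms, tmpl.atoms))
    assert disp == 0.0
    renamed = {a.seq_id: a.comp_id for a in chain.atoms}
    from templex.config import AA_ONE_TO_THREE
    assert renamed[4] == AA_ONE_TO_THREE[qseq[3]]
    assert chain.unaligned_template_positions == []


def test_sequence_replace_insertions_have_no_atoms(template_chain):
    tmpl, entry = template_chain
    tseq = entry.unitmol("A").sequence
    # query has a 3-residue insertion after position 5
    qseq = tseq[:5] + "GGG" + tseq[5:]
    pairs = [(i, i) for i in range(1, 6)] + [(i + 3, i) for i in range(6, 11)]
    aln = Alignment("q", ("9abc", "A"), pairs, 90.0, 1e-20, 100.0, 0, 0, qseq, tseq)
    chain = sequence_replace(tmpl, aln, qseq)
    present = {a.seq_id for a in chain.atoms}
    assert present.isdisjoint({6, 7, 8})  # inserted positions are missing
    assert {1, 2, 3, 4, 5, 9, 10, 11, 12, 13} == present


def test_sequence_replace_flags_unaligned_template_residues(template_chain):
    tmpl, entry = template_chain
    tseq = entry.unitmol("A").sequence
    aln = Alignment("q", ("9abc", "A"), [(i, i) for i in range(1, 6)],
                    50.0, 1e-10, 100.0, 0, 0, tseq[:5], tseq)
    chain = sequence_replace(tmpl, aln, tseq[:5])
    assert chain.unaligned_template_positions == [6, 7, 8, 9, 10]


def _dist_matrix(atoms):
    xyz = np.array([a.xyz for a in atoms])
    return np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)


def test_dock_identity_recovers_template(template_chain):
    tmpl, entry = template_chain
    seq = entry.unitmol("A").sequence
    model = template_based_dock([tmpl.atoms], [tmpl], [_identity_aln(seq)])
    assert model.chains[0].rmsd == pytest.approx(0.0, abs=1e-9)
    assert max(np.linalg.norm(a.xyz - b.xyz) for a, b in
               zip(model.chains[0].atoms, tmpl.atoms)) < 1e-9


def test_dock_rigidly_recovers_prerotated_query(template_chain):
    tmpl, entry = template_chain
    seq = entry.unitmol("A").sequence
    rot = Rotation.random(random_state=4).as_matrix()
    moved = [Atom(a.atom_name, a.element, a.comp_id, a.seq_id,
                  rot @ a.xyz + np.array([5.0, -3.0, 9.0]))
             for a in tmpl.atoms]
    model = template_based_dock([moved], [tmpl], [_identity_aln(seq)])
    assert model.chains[0].rmsd == pytest.approx(0.0, abs=1e-8)
    # docked chain sits back on the template
    assert max(np.linalg.norm(a.xyz - b.xyz) for a, b in
               zip(model.chains[0].atoms, tmpl.atoms)) < 1e-7
    # internal geometry of the query is untouched
    assert np.abs(_dist_matrix(model.chains[0].atoms) -
                  _dist_matrix(moved)).max() < 1e-6


def test_dock_needs_three_fittable_residues(template_chain):
    tmpl, entry = template_chain
    seq = entry.unitmol("A").sequence
    aln = Alignment("q", ("9abc", "A"), [(1, 1), (2, 2)], 10.0, 1e-5,
                    100.0, 0, 0, seq, seq)
    with pytest.raises(UndockableChainError):
        template_based_dock([tmpl.atoms], [tmpl], [aln])


def _cmpd(coords):
    n = len(coords)
    return CompoundGraph("QRY", [("C", 0, False)] * n,
                         [(i, i + 1, 1.0) for i in range(n - 1)],
                         np.array(coords, dtype=float))


def test_place_compound_rigid_recovery_and_rigidity():
    rng = np.random.default_rng(6)
    coords = rng.normal(size=(8, 3)) * 2
    tmpl = _cmpd(coords)
    query = _cmpd(coords + np.array([4.0, 1.0, -2.0]))
    corr = max_common_substructure(query, tmpl)
    placed, rmsd = place_compound_rigid(query, tmpl, corr)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.abs(placed - coords).max() < 1e-9
    d_before = np.linalg.norm(query.coords[:, None] - query.coords[None, :], axis=-1)
    d_after = np.linalg.norm(placed[:, None] - placed[None, :], axis=-1)
    assert np.abs(d_before - d_after).max() < 1e-6
    from templex.chem import AtomCorrespondence
    with pytest.raises(DegenerateFitError):
        place_compound_rigid(query, tmpl, AtomCorrespondence([(0, 0)], 1, 0.1))


def test_expand_to_biological_unit_adds_untransformed(simple_entry):
    entry, _ = simple_entry
    mols = build_assembly(entry, "1")
    tmpl = next(m for m in mols if m.asym_id == "A")
    seq = entry.unitmol("A").sequence
    from templex.modeling import SequenceReplacedModel
    chain = sequence_replace(tmpl, _identity_aln(seq), seq)
    model = SequenceReplacedModel("9abc", [chain])
    extras = expand_to_biological_unit(model, mols, [tmpl.key])
    assert [m.asym_id for m in extras] == ["B"]
    lig_src = entry.unitmol("B")
    assert all(np.allclose(a.xyz, b.xyz)
               for a, b in zip(extras[0].atoms, lig_src.atoms))


def test_modeller_script_and_pir_round_trip(simple_entry):
    entry, _ = simple_entry
    tmpl = build_assembly(entry, "1")[0]
    seq = entry.unitmol("A").sequence
    script, pir = emit_modeller_script([tmpl], [_identity_aln(seq)], "demo")
    from Bio import SeqIO
    records = list(SeqIO.parse(io.StringIO(pir), "pir"))
    assert [r.id for r in records] == ["demo_template", "demo_query"]
    assert str(records[0].seq) == str(records[1].seq) == seq
    assert "demo_template" in script and "demo.pir" in script

    # two-chain template: PIR carries a chain break
    _script2, pir2 = emit_modeller_script(
        [tmpl, tmpl], [_identity_aln(seq), _identity_aln(seq)], "dimer")
    body = [ln for ln in pir2.splitlines() if not ln.startswith((">", "structure", "sequence"))]
    assert any("/" in ln for ln in body)
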