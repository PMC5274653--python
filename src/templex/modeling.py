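"""Model generation from chosen templates.

Three model flavors are produced, in increasing order of input demands:

* *sequence-replaced model* — template coordinates with residue names and
  numbers rewritten to the query according to the alignment.  No atom moves,
  substituted side chains are not rebuilt, and query insertions have no
  atoms; this is a residue-resolution model generated instantly.
* *template-based docked model* — each query monomer structure is rigidly
  fitted (least-squares, Kabsch) onto its template chain via the Cα atoms of
  aligned residues and assembled in the template frame.  Monomer
  conformations are conserved exactly; inter-chain clashes are counted and
  reported, never repaired.
* *rigid compound placement* — a query compound with 3D coordinates is
  superposed onto the template compound over the MCS atom correspondence.

For full-atom modeling a MODELLER script plus PIR alignment is emitted as
text; this package never runs MODELLER.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .assembly import AsmblMol
from .chem import AtomCorrespondence, CompoundGraph
from .config import AA_ONE_TO_THREE
from .mmcif_model import Atom, UnitMol, write_unitmol_pdb
from .seqsearch import Alignment


class DegenerateFitError(ValueError):
    """Fewer than 3 points, or a collinear point set: no unique rotation."""


class UndockableChainError(ValueError):
    """A query chain lacks enough aligned fittable atoms."""


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of paired point sets.

    Returns (rotation, translation, rmsd) such that ``moving @ R.T + t``
    best fits ``fixed`` with a proper rotation; rmsd is the minimized value.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both be N x 3")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 paired points")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    mm = moving - cm
    ff = fixed - cf
    if np.linalg.matrix_rank(mm, tol=1e-8) < 2 or np.linalg.matrix_rank(ff, tol=1e-8) < 2:
        raise DegenerateFitError("collinear point set; rotation underdetermined")
    h = mm.T @ ff
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    diff = mm @ rot.T - ff
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# sequence-replaced models

@dataclasses.dataclass
class ReplacedChain:
    """One template chain with residue names/numbers rewritten to the query."""

    source_key: tuple[str, str, str]
    atoms: list[Atom]
    unaligned_template_positions: list[int]
    aln: Alignment


@dataclasses.dataclass
class SequenceReplacedModel:
    template_pdb_id: str
    chains: list[ReplacedChain]
    extra_molecules: list[AsmblMol] = dataclasses.field(default_factory=list)


def sequence_replace(
    template_mol: AsmblMol, aln: Alignment, query_seq: str
) -> ReplacedChain:
    """Rename/renumber aligned template residues to the query; move nothing.

    Unaligned template residues keep their original identity and are listed
    as flagged positions; query residues inserted relative to the template
    simply have no atoms.
    """
    t2q = aln.template_to_query()
    max_t = max(t2q) if t2q else 0
    n_template = len(aln.template_seq)
    if max_t > n_template:
        raise ValueError(
            f"alignment references template position {max_t} "
            f"beyond sequence length {n_template}")
    atoms_out: list[Atom] = []
    unaligned: set[int] = set()
    for a in template_mol.atoms:
        if a.seq_id is not None and a.seq_id in t2q:
            qpos = t2q[a.seq_id]
            comp = AA_ONE_TO_THREE.get(aln.query_seq[qpos - 1].upper(), "UNK")
            atoms_out.append(Atom(a.atom_name, a.element, comp, qpos,
                                  a.xyz.copy()))
        else:
            atoms_out.append(Atom(a.atom_name, a.element, a.comp_id, a.seq_id,
                                  a.xyz.copy()))
            if a.seq_id is not None:
                unaligned.add(a.seq_id)
    return ReplacedChain(template_mol.key, atoms_out, sorted(unaligned), aln)


# ---------------------------------------------------------------------------
# template-based docking

@dataclasses.dataclass
class DockedChain:
    atoms: list[Atom]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclasses.dataclass
class DockedModel:
    chains: list[DockedChain]
    clash_count: int
    extra_molecules: list[AsmblMol] = dataclasses.field(default_factory=list)


def _atoms_by_residue(atoms: Sequence[Atom]) -> dict[int, dict[str, Atom]]:
    table: dict[int, dict[str, Atom]] = {}
    for a in atoms:
        if a.seq_id is not None:
            table.setdefault(a.seq_id, {})[a.atom_name] = a
    return table


def count_clashes(chains: Sequence[Sequence[Atom]], threshold: float = 2.0) -> int:
    """Heavy-atom pairs closer than ``threshold`` between different chains."""
    n = 0
    heavy = [[a for a in ch if a.is_heavy] for ch in chains]
    trees = [cKDTree([a.xyz for a in ch]) if ch else None for ch in heavy]
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            if trees[i] is None or trees[j] is None:
                continue
            n += trees[i].count_neighbors(trees[j], threshold)
    return int(n)


def template_based_dock(
    query_structures: Sequence[Sequence[Atom]],
    templates: Sequence[AsmblMol],
    alignments: Sequence[Alignment],
    fit_atoms: str = "CA",
    clash_threshold: float = 2.0,
) -> DockedModel:
    """Assemble query monomer structures in the template complex frame.

    Each query chain is fitted by least squares on the ``fit_atoms``
    ("CA" or "all" heavy atoms) of aligned residues present in both query
    and template, then all its atoms are transformed; internal geometry is
    untouched.  Inter-chain clashes of the assembled model are counted.
    """
    if not (len(query_structures) == len(templates) == len(alignments)):
        raise ValueError("one query structure, template and alignment per chain")
    chains: list[DockedChain] = []
    for q_atoms, tmpl, aln in zip(query_structures, templates, alignments):
        q_res = _atoms_by_residue(q_atoms)
        t_res = _atoms_by_residue(tmpl.atoms)
        moving, fixed = [], []
        for qpos, tpos in aln.pairs:
            if qpos not in q_res or tpos not in t_res:
                continue
            if fit_atoms == "CA":
                qa, ta = q_res[qpos].get("CA"), t_res[tpos].get("CA")
                if qa is not None and ta is not None:
                    moving.append(qa.xyz)
                    fixed.append(ta.xyz)
            else:
                for name, qa in q_res[qpos].items():
                    ta = t_res[tpos].get(name)
                    if ta is not None and qa.is_heavy:
                        moving.append(qa.xyz)
                        fixed.append(ta.xyz)
        if len(moving) < 3:
            raise UndockableChainError(
                f"chain on template {tmpl.key}: only {len(moving)} aligned "
                "fittable atoms (need >= 3)")
        try:
            rot, trans, rmsd = kabsch_superpose(np.array(moving), np.array(fixed))
        except DegenerateFitError as exc:
            raise UndockableChainError(
                f"chain on template {tmpl.key}: {exc}") from exc
        placed = [Atom(a.atom_name, a.element, a.comp_id, a.seq_id,
                       rot @ a.xyz + trans) for a in q_atoms]
        chains.append(DockedChain(placed, rot, trans, rmsd))
    clash = count_clashes([c.atoms for c in chains], clash_threshold)
    return DockedModel(chains, clash)


def place_compound_rigid(
    query_cmpd: CompoundGraph,
    template_cmpd: CompoundGraph,
    corr: AtomCorrespondence,
) -> tuple[np.ndarray, float]:
    """Superpose a query compound onto a template via MCS atom pairs.

    Rigid placement: the query conformation is unchanged.  Returns the
    transformed query coordinates and the rmsd over matched atoms.
    """
    if corr.size < 3:
        raise DegenerateFitError(
            f"only {corr.size} matched atoms; rigid placement needs >= 3 "
            "(place the compound manually)")
    if query_cmpd.coords is None or template_cmpd.coords is None:
        raise ValueError("both compounds need 3D coordinates")
    moving = query_cmpd.coords[[q for q, _ in corr.pairs]]
    fixed = template_cmpd.coords[[t for _, t in corr.pairs]]
    rot, trans, rmsd = kabsch_superpose(moving, fixed)
    return query_cmpd.coords @ rot.T + trans, rmsd


# ---------------------------------------------------------------------------
# biological-unit expansion

def expand_to_biological_unit(
    model: SequenceReplacedModel | DockedModel,
    assembly_mols: Sequence[AsmblMol],
    assigned_keys: Sequence[tuple[str, str, str]],
) -> list[AsmblMol]:
    """Add every assembly molecule with no query assignment, untransformed.

    Returns the added molecules (also appended to ``model.extra_molecules``);
    no existing atom is moved.
    """
    assigned = set(assigned_keys)
    extras = [m for m in assembly_mols if m.key not in assigned]
    model.extra_molecules.extend(extras)
    return extras


# ---------------------------------------------------------------------------
# output

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def model_to_pdb(
    chains: Sequence[Sequence[Atom]],
    remarks: Sequence[str] = (),
    polymer_flags: Optional[Sequence[bool]] = None,
) -> str:
    """Multi-chain classical PDB text with a remark block."""
    lines = [f"REMARK 300 {r}" for r in remarks]
    serial = 0
    for ci, atoms in enumerate(chains):
        chain_id = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        polymer = polymer_flags[ci] if polymer_flags else True
        record = "ATOM" if polymer else "HETATM"
        for a in atoms:
            serial += 1
            name = a.atom_name
            if len(name) < 4 and len(a.element) == 1:
                name = " " + name
            seq = a.seq_id if a.seq_id is not None else 1
            lines.append(
                f"{record:<6s}{serial:5d} {name:<4.4s} {a.comp_id:>3.3s} "
                f"{chain_id}{seq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}"
                f"{a.xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{a.element.upper():>2.2s}"
            )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def identity_remark(aln: Alignment) -> str:
    """The 'contact-site/overall' identity pair, e.g. '79.4/68.6'."""
    contact = "-" if aln.identity_contact is None else f"{aln.identity_contact:.1f}"
    return f"{contact}/{aln.identity_all:.1f}"


# ---------------------------------------------------------------------------
# MODELLER script emission

def _gapped_strings(aln: Alignment) -> tuple[str, str]:
    """Expand an alignment into gapped query/template strings of equal length."""
    q, t = aln.query_seq, aln.template_seq
    out_q, out_t = [], []
    qi, ti = 1, 1
    for qp, tp in aln.pairs:
        while qi < qp:
            out_q.append(q[qi - 1])
            out_t.append("-")
            qi += 1
        while ti < tp:
            out_q.append("-")
            out_t.append(t[ti - 1])
            ti += 1
        out_q.append(q[qp - 1])
        out_t.append(t[tp - 1])
        qi, ti = qp + 1, tp + 1
    while qi <= len(q):
        out_q.append(q[qi - 1])
        out_t.append("-")
        qi += 1
    while ti <= len(t):
        out_q.append("-")
        out_t.append(t[ti - 1])
        ti += 1
    return "".join(out_q), "".join(out_t)


def _wrap(seq: str, width: int = 75) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def emit_modeller_script(
    templates: Sequence[AsmblMol],
    alignments: Sequence[Alignment],
    basename: str = "model",
) -> tuple[str, str]:
    """Emit (driver script text, PIR alignment text) for full-atom modeling.

    Multi-chain templates produce a single PIR entry with '/' chain breaks.
    The script references the template PDB file ``<basename>_template.pdb``
    and is plain text: it is never executed by this package.
    """
    if len(templates) != len(alignments):
        raise ValueError("one alignment per template chain")
    q_parts, t_parts = [], []
    for aln in alignments:
        gq, gt = _gapped_strings(aln)
        q_parts.append(gq)
        t_parts.append(gt)
    template_file = f"{basename}_template"
    pir = (
        f">P1;{template_file}\n"
        f"structureX:{template_file}:FIRST:@:LAST:@::::\n"
        f"{_wrap('/'.join(t_parts))}*\n"
        f">P1;{basename}_query\n"
        f"sequence:{basename}_query:::::::0.00:0.00\n"
        f"{_wrap('/'.join(q_parts))}*\n"
    )
    script = (
        "from modeller import Environ\n"
        "from modeller.automodel import AutoModel\n\n"
        "env = Environ()\n"
        "env.io.atom_files_directory = ['.']\n"
        f"a = AutoModel(env, alnfile='{basename}.pir',\n"
        f"              knowns=('{template_file}',),\n"
        f"              sequence='{basename}_query')\n"
        "a.starting_model = 1\n"
        "a.ending_model = 1\n"
        "a.make()\n"
    )
    return script, pir


def unitmol_pdb(u: UnitMol) -> str:  # convenience re-export used by the CLI
    return write_unitmol_pdb(u)
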