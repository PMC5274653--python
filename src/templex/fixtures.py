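"""Synthetic mmCIF entries with known ground truth.

The generator lays out idealized polypeptide chains (compact five-atom
residues along a helically twisted axis), places ligands and metals at
prescribed
distances from prescribed residues, declares symmetry operators and
biological-unit candidates, and emits a well-formed PDBx/mmCIF text plus a
ground-truth record: the expected unit molecules, assembly molecules per
biological unit and exact residue-level contacts at the 4 Å cutoff.

The ground truth is computed here by plain all-pairs distance scans and by
sequentially applying the generator's own operator matrices to coordinates —
deliberately independent of the package's KD-tree contact search and matrix
composition, so pipeline-closure tests compare two separate routes.

Everything is reproducible: the same spec (including its seed) yields
byte-identical mmCIF text.
"""

from __future__ import annotations

import dataclasses
import math
import re
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .config import AA_ONE_TO_THREE

RESIDUE_SPACING = 4.8  # Å between residue centers along the chain axis

# atom-name -> offset from the residue center; compact (<1.4 Å) so that a
# ligand placed d Å from a CA cannot accidentally touch neighboring residues.
# Offsets are twisted helically per residue so CA positions are never
# collinear (a collinear chain would make rigid fitting degenerate).
_RESIDUE_ATOMS = {
    "N": (-0.62, -0.35, 0.00),
    "CA": (0.00, 0.45, 0.00),
    "C": (0.62, -0.35, 0.00),
    "O": (0.62, -1.05, 0.35),
    "CB": (0.00, 1.15, 0.55),
}
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_TWIST_DEG = 100.0  # per-residue rotation of the offsets about the chain axis

_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


class FixtureSpecError(ValueError):
    pass


@dataclasses.dataclass
class ChainSpec:
    asym_id: str
    length: int
    sequence: Optional[str] = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    missing: tuple[int, ...] = ()  # label_seq_ids with no modeled atoms


@dataclasses.dataclass
class HetSpec:
    """A ligand/metal placed at a given distance from a chain residue's CA."""

    asym_id: str
    comp_id: str
    elements: tuple[str, ...]
    near: tuple[str, int, float]  # (chain asym_id, seq_id, distance Å)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    spread: float = 0.8  # Å between successive atoms of a multi-atom ligand


@dataclasses.dataclass
class OperSpec:
    oper_id: str
    rot_z_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        th = math.radians(self.rot_z_deg)
        rot = np.array([
            [math.cos(th), -math.sin(th), 0.0],
            [math.sin(th), math.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ])
        return rot, np.array(self.translation, dtype=float)


@dataclasses.dataclass
class AssemblySpec:
    assembly_id: str
    rows: list[tuple[tuple[str, ...], str]]  # (asym_ids, oper_expression)


@dataclasses.dataclass
class FixtureSpec:
    pdb_id: str = "9zzz"
    chains: list[ChainSpec] = dataclasses.field(default_factory=list)
    hets: list[HetSpec] = dataclasses.field(default_factory=list)
    operators: list[OperSpec] = dataclasses.field(
        default_factory=lambda: [OperSpec("1")])
    assemblies: Optional[list[AssemblySpec]] = None
    include_waters: bool = False
    declare_entity_poly: bool = True
    contact_cutoff: float = 4.0
    seed: int = 0


# ---------------------------------------------------------------------------
# geometry

def _chain_atoms(spec: ChainSpec, sequence: str) -> list[tuple[str, str, str, int, np.ndarray]]:
    """(atom_name, element, comp_id, seq_id, xyz) for one chain."""
    atoms = []
    origin = np.array(spec.origin, dtype=float)
    for i in range(1, spec.length + 1):
        if i in spec.missing:
            continue
        center = origin + np.array([i * RESIDUE_SPACING, 0.0, 0.0])
        comp = AA_ONE_TO_THREE.get(sequence[i - 1], "UNK")
        th = math.radians(_TWIST_DEG * i)
        twist = np.array([[1.0, 0.0, 0.0],
                          [0.0, math.cos(th), -math.sin(th)],
                          [0.0, math.sin(th), math.cos(th)]])
        for name, off in _RESIDUE_ATOMS.items():
            atoms.append((name, _ELEMENT_OF[name], comp, i,
                          center + twist @ np.array(off)))
    return atoms


def _het_atoms(spec: HetSpec, chain_ca: dict[tuple[str, int], np.ndarray]):
    chain_asym, seq_id, dist = spec.near
    if dist <= 0:
        raise FixtureSpecError(f"het {spec.asym_id}: non-positive distance")
    try:
        anchor = chain_ca[(chain_asym, seq_id)]
    except KeyError:
        raise FixtureSpecError(
            f"het {spec.asym_id}: anchor residue {chain_asym}:{seq_id} "
            "does not exist") from None
    direction = np.array(spec.direction, dtype=float)
    direction /= np.linalg.norm(direction)
    base = anchor + dist * direction
    atoms = []
    for k, elem in enumerate(spec.elements):
        # extra atoms extend away from the chain, never toward neighbors
        pos = base + k * spec.spread * direction
        atoms.append((f"{elem.upper()}{k + 1}", elem.upper(),
                      spec.comp_id, None, pos))
    return atoms


# ---------------------------------------------------------------------------
# independent operator-expression expansion (ground-truth route)

_GT_RANGE = re.compile(r"^(\d+)-(\d+)$")


def _gt_expand(expr: str) -> list[list[str]]:
    """Expand an expression into lists of oper_ids, one list per label."""
    expr = expr.strip()
    groups = re.findall(r"\(([^)]*)\)", expr) if "(" in expr else [expr]
    per_group: list[list[str]] = []
    for g in groups:
        ids: list[str] = []
        for item in g.split(","):
            item = item.strip()
            m = _GT_RANGE.match(item)
            if m:
                ids.extend(str(k) for k in range(int(m.group(1)), int(m.group(2)) + 1))
            else:
                ids.append(item)
        per_group.append(ids)
    combos: list[list[str]] = [[i] for i in per_group[0]]
    for group in per_group[1:]:
        combos = [c + [j] for c in combos for j in group]
    return combos


def _gt_transform(coords: np.ndarray, parts: Sequence[str],
                  opers: dict[str, OperSpec]) -> np.ndarray:
    """Apply the operator chain to points, rightmost id first."""
    out = coords.copy()
    for oper_id in reversed(parts):
        rot, trans = opers[oper_id].matrices()
        out = out @ rot.T + trans
    return out


# ---------------------------------------------------------------------------
# mmCIF emission

def _fmt(x: float, prec: int = 3) -> str:
    return f"{x:.{prec}f}"


def make_entry(spec: FixtureSpec) -> tuple[str, dict]:
    """Generate (mmCIF text, ground-truth record) for one synthetic entry."""
    if not spec.chains:
        raise FixtureSpecError("at least one chain is required")
    rng = np.random.default_rng(spec.seed)

    sequences: dict[str, str] = {}
    for ch in spec.chains:
        if ch.sequence is not None:
            if len(ch.sequence) != ch.length:
                raise FixtureSpecError(
                    f"chain {ch.asym_id}: sequence length != declared length")
            sequences[ch.asym_id] = ch.sequence.upper()
        else:
            sequences[ch.asym_id] = "".join(
                rng.choice(list(_AA_LETTERS), size=ch.length))

    # atoms per asym, plus the CA lookup for het anchoring
    mol_atoms: dict[str, list] = {}
    chain_ca: dict[tuple[str, int], np.ndarray] = {}
    for ch in spec.chains:
        atoms = _chain_atoms(ch, sequences[ch.asym_id])
        mol_atoms[ch.asym_id] = atoms
        for name, _e, _c, seq_id, xyz in atoms:
            if name == "CA":
                chain_ca[(ch.asym_id, seq_id)] = xyz
    for het in spec.hets:
        if het.asym_id in mol_atoms:
            raise FixtureSpecError(f"duplicate asym_id {het.asym_id}")
        mol_atoms[het.asym_id] = _het_atoms(het, chain_ca)

    asym_order = [ch.asym_id for ch in spec.chains] + [h.asym_id for h in spec.hets]
    assemblies = spec.assemblies or [
        AssemblySpec("1", [(tuple(asym_order), spec.operators[0].oper_id)])
    ]
    opers = {op.oper_id: op for op in spec.operators}
    for a in assemblies:
        for asyms, expr in a.rows:
            for asym in asyms:
                if asym not in mol_atoms:
                    raise FixtureSpecError(f"assembly {a.assembly_id}: "
                                           f"unknown asym_id {asym}")
            for parts in _gt_expand(expr):
                for oper_id in parts:
                    if oper_id not in opers:
                        raise FixtureSpecError(
                            f"assembly {a.assembly_id}: undeclared oper {oper_id}")

    text = _emit_mmcif(spec, sequences, mol_atoms, assemblies)
    truth = _ground_truth(spec, mol_atoms, assemblies, opers)
    return text, truth


def _emit_mmcif(spec, sequences, mol_atoms, assemblies) -> str:
    lines = [f"data_{spec.pdb_id}", f"_entry.id {spec.pdb_id}", ""]

    entity_of: dict[str, str] = {}
    entities = []  # (id, type, description)
    for i, ch in enumerate(spec.chains, start=1):
        entity_of[ch.asym_id] = str(i)
        entities.append((str(i), "polymer", f"synthetic chain {ch.asym_id}"))
    base = len(spec.chains)
    for j, het in enumerate(spec.hets, start=1):
        entity_of[het.asym_id] = str(base + j)
        entities.append((str(base + j), "non-polymer", f"synthetic ligand {het.comp_id}"))
    water_entity = None
    if spec.include_waters:
        water_entity = str(base + len(spec.hets) + 1)
        entities.append((water_entity, "water", "water"))

    lines += ["loop_", "_entity.id", "_entity.type", "_entity.pdbx_description"]
    for eid, etype, desc in entities:
        lines.append(f"{eid} {etype} '{desc}'")
    lines.append("")

    if spec.declare_entity_poly and spec.chains:
        lines += ["loop_", "_entity_poly.entity_id", "_entity_poly.type",
                  "_entity_poly.pdbx_seq_one_letter_code_can"]
        for ch in spec.chains:
            lines.append(f"{entity_of[ch.asym_id]} 'polypeptide(L)' "
                         f"{sequences[ch.asym_id]}")
        lines.append("")

    lines += ["loop_", "_struct_asym.id", "_struct_asym.entity_id"]
    for asym in mol_atoms:
        lines.append(f"{asym} {entity_of[asym]}")
    if spec.include_waters:
        lines.append(f"W {water_entity}")
    lines.append("")

    lines += ["loop_", "_pdbx_struct_assembly.id", "_pdbx_struct_assembly.details"]
    for a in assemblies:
        lines.append(f"{a.assembly_id} author_defined_assembly")
    lines.append("")

    lines += ["loop_", "_pdbx_struct_assembly_gen.assembly_id",
              "_pdbx_struct_assembly_gen.oper_expression",
              "_pdbx_struct_assembly_gen.asym_id_list"]
    for a in assemblies:
        for asyms, expr in a.rows:
            asym_list = ",".join(asyms)
            if spec.include_waters:
                asym_list += ",W"
            lines.append(f"{a.assembly_id} '{expr}' {asym_list}")
    lines.append("")

    lines += ["loop_", "_pdbx_struct_oper_list.id"]
    lines += [f"_pdbx_struct_oper_list.matrix[{i}][{j}]"
              for i in (1, 2, 3) for j in (1, 2, 3)]
    lines += [f"_pdbx_struct_oper_list.vector[{i}]" for i in (1, 2, 3)]
    for op in spec.operators:
        rot, trans = op.matrices()
        nums = " ".join(f"{v:.9f}" for v in rot.flatten())
        vec = " ".join(f"{v:.9f}" for v in trans)
        lines.append(f"{op.oper_id} {nums} {vec}")
    lines.append("")

    lines += ["loop_", "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.type_symbol", "_atom_site.label_atom_id",
              "_atom_site.label_comp_id", "_atom_site.label_asym_id",
              "_atom_site.label_entity_id", "_atom_site.label_seq_id",
              "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
              "_atom_site.occupancy"]
    serial = 0
    is_het = {h.asym_id for h in spec.hets}
    for asym, atoms in mol_atoms.items():
        group = "HETATM" if asym in is_het else "ATOM"
        for name, elem, comp, seq_id, xyz in atoms:
            serial += 1
            seq = str(seq_id) if seq_id is not None else "."
            lines.append(
                f"{group} {serial} {elem} {name} {comp} {asym} "
                f"{entity_of[asym]} {seq} {_fmt(xyz[0])} {_fmt(xyz[1])} "
                f"{_fmt(xyz[2])} 1.00")
    if spec.include_waters:
        for k in range(3):
            serial += 1
            lines.append(
                f"HETATM {serial} O O HOH W {water_entity} . "
                f"{_fmt(200.0 + 5 * k)} {_fmt(200.0)} {_fmt(200.0)} 1.00")
    lines.append("#")
    return "\n".join(lines) + "\n"


def _ground_truth(spec, mol_atoms, assemblies, opers) -> dict:
    heavy = {
        asym: (
            np.array([xyz for _n, _e, _c, _s, xyz in atoms]),
            [s if s is not None else 1 for _n, _e, _c, s, _x in atoms],
        )
        for asym, atoms in mol_atoms.items()
    }
    truth: dict = {
        "pdb_id": spec.pdb_id,
        "n_unitmols": len(mol_atoms),
        "unitmol_asym_ids": sorted(mol_atoms),
        "assemblies": {},
    }
    for a in assemblies:
        placed: dict[tuple[str, str], tuple[np.ndarray, list[int]]] = {}
        for asyms, expr in a.rows:
            for parts in _gt_expand(expr):
                label = "-".join(parts)
                for asym in asyms:
                    coords, seq_ids = heavy[asym]
                    placed[(asym, label)] = (
                        _gt_transform(coords, parts, opers), seq_ids)
        keys = sorted(placed)
        contacts = []
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                ca, sa = placed[ka]
                cb, sb = placed[kb]
                mask = cdist(ca, cb) <= spec.contact_cutoff
                if mask.any():
                    res_a = sorted({sa[r] for r in np.nonzero(mask.any(axis=1))[0]})
                    res_b = sorted({sb[c] for c in np.nonzero(mask.any(axis=0))[0]})
                    contacts.append({
                        "mol_a": list(ka), "mol_b": list(kb),
                        "seq_ids_a": res_a, "seq_ids_b": res_b,
                    })
        truth["assemblies"][a.assembly_id] = {
            "n_asmblmols": len(placed),
            "asmblmol_keys": [list(k) for k in keys],
            "contacts": contacts,
        }
    return truth


# ---------------------------------------------------------------------------
# sequence fixtures

def make_homolog_pair(
    seq_len: int, identity_target: float, seed: int = 0
) -> tuple[str, str]:
    """A sequence pair whose identity equals the target within one substitution."""
    if not 0 <= identity_target <= 100:
        raise FixtureSpecError("identity target must be in [0, 100]")
    rng = np.random.default_rng(seed)
    s1 = "".join(rng.choice(list(_AA_LETTERS), size=seq_len))
    n_sub = round(seq_len * (100.0 - identity_target) / 100.0)
    positions = rng.choice(seq_len, size=n_sub, replace=False)
    s2 = list(s1)
    for p in positions:
        choices = [c for c in _AA_LETTERS if c != s2[p]]
        s2[p] = choices[rng.integers(len(choices))]
    return s1, "".join(s2)


# ---------------------------------------------------------------------------
# ready-made study set

def demo_specs(n_entries: int = 20, seed: int = 0) -> list[FixtureSpec]:
    """A varied deterministic batch of fixture specs exercising every stage.

    Entries cycle through: monomer+ligand, homodimer via translation
    operator, heterodimer with metal, rotation+translation assembly with two
    candidates, and a chain with unmodelled residues plus a precipitant-like
    ligand.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n_entries):
        pdb_id = f"9x{k:02d}"
        kind = k % 5
        base_seed = int(rng.integers(1, 2**31 - 1))
        if kind == 0:
            length = 10 + k % 7
            specs.append(FixtureSpec(
                pdb_id=pdb_id,
                chains=[ChainSpec("A", length)],
                hets=[HetSpec("B", "LIG", ("C", "N", "O"),
                              near=("A", 1 + k % length, 3.5))],
                seed=base_seed))
        elif kind == 1:
            length = 12 + k % 5
            specs.append(FixtureSpec(
                pdb_id=pdb_id,
                chains=[ChainSpec("A", length)],
                operators=[OperSpec("1"), OperSpec("2", translation=(0, 3.6, 0))],
                assemblies=[AssemblySpec("1", [(("A",), "1,2")])],
                seed=base_seed))
        elif kind == 2:
            la, lb = 10 + k % 4, 14 + k % 3
            specs.append(FixtureSpec(
                pdb_id=pdb_id,
                chains=[ChainSpec("A", la),
                        ChainSpec("B", lb, origin=(0.0, 3.6, 0.0))],
                hets=[HetSpec("C", "ZN", ("ZN",), near=("A", 2 + k % 5, 2.3))],
                seed=base_seed))
        elif kind == 3:
            length = 9 + k % 6
            specs.append(FixtureSpec(
                pdb_id=pdb_id,
                chains=[ChainSpec("A", length)],
                hets=[HetSpec("B", "ATP", ("C", "C", "N", "O", "P"),
                              near=("A", 3, 3.2))],
                operators=[OperSpec("1"),
                           OperSpec("2", rot_z_deg=180.0, translation=(0, 7.0, 0)),
                           OperSpec("3", translation=(0, 0, 40.0))],
                assemblies=[
                    AssemblySpec("1", [(("A", "B"), "(1-2)")]),
                    AssemblySpec("2", [(("A", "B"), "1,3")]),
                ],
                include_waters=True,
                seed=base_seed))
        else:
            length = 15 + k % 4
            specs.append(FixtureSpec(
                pdb_id=pdb_id,
                chains=[ChainSpec("A", length, missing=(5,))],
                hets=[HetSpec("B", "GOL", ("C", "O", "C"),
                              near=("A", length - 2, 3.8))],
                include_waters=True,
                seed=base_seed))
    return specs
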