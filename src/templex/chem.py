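"""2D chemical similarity search and atom correspondences.

Compounds are compared on their heavy-atom graphs in two stages: a fast
*atom-pair descriptor* — the multiset of (atom class, atom class,
topological distance) triples over all heavy-atom pairs, compared with the
multiset Tanimoto coefficient — and a *maximum common substructure* (MCS)
search that yields explicit atom correspondences for rigid compound
placement.  The atom class is (element, heavy-neighbor count, aromaticity)
and topological distances are capped at 10 bonds; this descriptor dialect is
declared in :data:`DESCRIPTOR_DIALECT` and should accompany every reported
similarity value, since atom-pair dialects differ between programs.

The MCS is found by a connected build-up/backtracking search: element-
consistent, bond orders not compared (aromatic/single ambiguity across
formats), deterministic tie-breaking by lexicographically smallest pair
list, with a node budget that flags best-found results as approximate when
exhausted.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

DESCRIPTOR_DIALECT = "atom-pair[(element,heavy-degree,aromatic);topological-distance<=10]"


class CompoundReadError(ValueError):
    pass


class UnknownComponentError(KeyError):
    pass


@dataclasses.dataclass
class CompoundGraph:
    """Heavy-atom graph of one chemical compound.

    ``atoms`` holds (element, formal_charge, aromatic) triples; hydrogens
    are excluded.  3D coordinates (Å) are kept when the source had them.
    """

    label: str
    atoms: list[tuple[str, int, bool]]
    bonds: list[tuple[int, int, float]]
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise CompoundReadError(f"{self.label}: no heavy atoms")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise CompoundReadError(f"{self.label}: bond ({i},{j}) out of range")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def neighbors(self) -> list[set[int]]:
        nb: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j, _ in self.bonds:
            nb[i].add(j)
            nb[j].add(i)
        return nb

    def atom_classes(self) -> list[tuple[str, int, bool]]:
        nb = self.neighbors()
        return [(el, len(nb[i]), arom)
                for i, (el, _q, arom) in enumerate(self.atoms)]


@dataclasses.dataclass
class AtomCorrespondence:
    """An element-consistent partial injection between two compound graphs."""

    pairs: list[tuple[int, int]]
    size: int
    tanimoto_mcs: float
    approximate: bool = False


# ---------------------------------------------------------------------------
# reading

def from_rdkit(mol, label: str = "compound") -> CompoundGraph:
    """Convert an RDKit molecule to a heavy-atom CompoundGraph."""
    from rdkit import Chem

    if mol is None:
        raise CompoundReadError(f"{label}: RDKit could not parse the input")
    try:
        mol = Chem.RemoveHs(mol, sanitize=False)
        Chem.SanitizeMol(mol, catchErrors=True)
    except Exception:
        pass
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    index = {old: new for new, old in enumerate(heavy)}
    atoms = []
    for idx in heavy:
        a = mol.GetAtomWithIdx(idx)
        atoms.append((a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic()))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in index and j in index:
            bonds.append((index[i], index[j], float(b.GetBondTypeAsDouble())))
    coords = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        if conf.Is3D() or True:  # keep 2D layouts too; placement checks 3D itself
            coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy])
    return CompoundGraph(label, atoms, bonds, coords)


def read_compound(
    source: str | Path,
    fmt: Optional[str] = None,
    component_db: Optional[dict[str, "CompoundGraph"]] = None,
    label: Optional[str] = None,
) -> CompoundGraph:
    """Read a compound from SDF/MOL2/PDB file, SMILES string or comp_id.

    The format is inferred from the file suffix when ``fmt`` is not given;
    a short alphanumeric token is resolved as a three-letter component code
    against ``component_db`` before being tried as SMILES.
    """
    from rdkit import Chem

    src = str(source)
    path = Path(src)
    if fmt is None and path.suffix.lower() in (".sdf", ".mol", ".mol2", ".pdb") and path.exists():
        fmt = path.suffix.lower().lstrip(".")
        fmt = "sdf" if fmt == "mol" else fmt
    if fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolFile(src, removeHs=False, sanitize=False) \
            if path.exists() else Chem.MolFromMolBlock(src, removeHs=False, sanitize=False)
        return from_rdkit(mol, label or (path.stem if path.exists() else "compound"))
    if fmt == "mol2":
        mol = Chem.MolFromMol2File(src, removeHs=False, sanitize=False)
        return from_rdkit(mol, label or path.stem)
    if fmt == "pdb":
        text = path.read_text() if path.exists() else src
        mol = Chem.MolFromPDBBlock(text, removeHs=False, sanitize=False)
        if mol is not None and mol.GetNumBonds() == 0:
            warnings.warn("PDB het group has no bonds; perceiving connectivity",
                          stacklevel=2)
            from rdkit.Chem import rdDetermineBonds
            try:
                rdDetermineBonds.DetermineConnectivity(mol)
            except Exception:
                pass
        return from_rdkit(mol, label or path.stem)
    if fmt == "smiles":
        return from_rdkit(Chem.MolFromSmiles(src), label or "smiles")
    # no explicit format: comp_id lookup, then SMILES
    token = src.strip().upper()
    if component_db is not None and len(token) <= 5 and token.isalnum():
        if token in component_db:
            return component_db[token]
        raise UnknownComponentError(f"unknown component code {token!r}")
    mol = Chem.MolFromSmiles(src)
    if mol is None:
        raise CompoundReadError(f"cannot interpret {src!r} as SMILES")
    return from_rdkit(mol, label or "smiles")


def compound_from_unitmol(u) -> CompoundGraph:
    """Build a CompoundGraph (with 3D coordinates) from a het unit molecule."""
    from rdkit import Chem
    from rdkit.Chem import rdDetermineBonds
    from rdkit.Geometry import Point3D

    heavy = [a for a in u.atoms if a.is_heavy]
    mol = Chem.RWMol()
    conf = Chem.Conformer(len(heavy))
    for i, a in enumerate(heavy):
        mol.AddAtom(Chem.Atom(a.element.capitalize()))
        conf.SetAtomPosition(i, Point3D(*map(float, a.xyz)))
    mol.AddConformer(conf)
    m = mol.GetMol()
    try:
        rdDetermineBonds.DetermineConnectivity(m)
    except Exception:
        warnings.warn(f"{u.comp_id}: bond perception failed", stacklevel=2)
    return from_rdkit(m, u.comp_id or f"{u.pdb_id}_{u.asym_id}")


# ---------------------------------------------------------------------------
# atom-pair descriptor

def atom_pair_descriptor(g: CompoundGraph, max_dist: int = 10) -> Counter:
    """Multiset of (class_i, class_j, topological distance) atom-pair triples.

    Pairs across disconnected components are omitted (with a warning), so a
    disconnected input yields per-component descriptors.
    """
    classes = g.atom_classes()
    graph = g.graph()
    if g.n_atoms > 1 and not nx.is_connected(graph):
        warnings.warn(f"{g.label}: disconnected heavy-atom graph; "
                      "descriptor covers within-component pairs only", stacklevel=2)
    desc: Counter = Counter()
    for i, lengths in nx.all_pairs_shortest_path_length(graph):
        for j, d in lengths.items():
            if j <= i or d == 0:
                continue
            ci, cj = sorted((classes[i], classes[j]))
            desc[(ci, cj, min(d, max_dist))] += 1
    return desc


def descriptor_tanimoto(d1: Counter, d2: Counter) -> float:
    """Multiset Tanimoto: Σ min(count) / Σ max(count); symmetric."""
    if not d1 and not d2:
        warnings.warn("both descriptors empty; Tanimoto defined as 0", stacklevel=2)
        return 0.0
    keys = set(d1) | set(d2)
    num = sum(min(d1[k], d2[k]) for k in keys)
    den = sum(max(d1[k], d2[k]) for k in keys)
    return num / den


# ---------------------------------------------------------------------------
# maximum common substructure

class _MCSSearch:
    def __init__(self, q: CompoundGraph, t: CompoundGraph, node_budget: int):
        self.eq = [c[0] for c in q.atoms]
        self.et = [c[0] for c in t.atoms]
        self.nq = q.n_atoms
        self.nt = t.n_atoms
        self.adj_q = q.neighbors()
        self.adj_t = t.neighbors()
        self.budget = node_budget
        self.nodes = 0
        self.exhausted = False
        self.best_pairs: list[tuple[int, int]] = []

    def _consider(self, mapping: list[tuple[int, int]]) -> None:
        if len(mapping) > len(self.best_pairs):
            self.best_pairs = sorted(mapping)
        elif len(mapping) == len(self.best_pairs) and mapping:
            cand = sorted(mapping)
            if cand < self.best_pairs:
                self.best_pairs = cand

    def _candidates(self, mapping, used_q, used_t, forbidden):
        cands = []
        for qi, tj in mapping:
            for qa in self.adj_q[qi]:
                if qa in used_q:
                    continue
                for ta in self.adj_t[tj]:
                    if ta in used_t or self.eq[qa] != self.et[ta]:
                        continue
                    p = (qa, ta)
                    if p not in forbidden:
                        cands.append(p)
        return sorted(set(cands))

    def _extend(self, mapping, used_q, used_t, forbidden) -> None:
        self.nodes += 1
        if self.nodes > self.budget:
            self.exhausted = True
            return
        self._consider(mapping)
        bound = len(mapping) + min(self.nq - len(used_q), self.nt - len(used_t))
        if bound <= len(self.best_pairs):
            return
        cands = self._candidates(mapping, used_q, used_t, forbidden)
        local_forbidden = set(forbidden)
        for p in cands:
            if self.exhausted:
                return
            qa, ta = p
            mapping.append(p)
            used_q.add(qa)
            used_t.add(ta)
            self._extend(mapping, used_q, used_t, local_forbidden)
            mapping.pop()
            used_q.discard(qa)
            used_t.discard(ta)
            local_forbidden.add(p)

    def run(self) -> list[tuple[int, int]]:
        seeds = sorted(
            (qi, tj) for qi in range(self.nq) for tj in range(self.nt)
            if self.eq[qi] == self.et[tj]
        )
        forbidden: set[tuple[int, int]] = set()
        for seed in seeds:
            if self.exhausted:
                break
            if 1 + min(self.nq - 1, self.nt - 1) <= len(self.best_pairs):
                break
            self._extend([seed], {seed[0]}, {seed[1]}, forbidden)
            forbidden.add(seed)
        return self.best_pairs


def max_common_substructure(
    q: CompoundGraph, t: CompoundGraph, node_budget: int = 500_000
) -> AtomCorrespondence:
    """Largest connected common subgraph of two compound graphs.

    Elements must match; bond orders are not compared.  The search is exact
    within the node budget; on exhaustion the best correspondence found so
    far is returned flagged approximate.
    """
    search = _MCSSearch(q, t, node_budget)
    pairs = search.run()
    size = len(pairs)
    denom = q.n_atoms + t.n_atoms - size
    return AtomCorrespondence(
        pairs=pairs,
        size=size,
        tanimoto_mcs=size / denom if denom else 0.0,
        approximate=search.exhausted,
    )


# ---------------------------------------------------------------------------
# similarity search

def search_similar_compounds(
    query: CompoundGraph,
    db: dict[str, CompoundGraph],
    tanimoto_min: float = 0.7,
) -> list[tuple[str, float]]:
    """Rank database compounds by atom-pair-descriptor Tanimoto.

    Returns (comp_id, tanimoto) with tanimoto ≥ ``tanimoto_min``, highest
    first (ties by comp_id).  The 0.7 default reflects the empirical rule
    that >0.7 2D similarity predicts a template conformation within 2 Å.
    """
    if not db:
        raise ValueError("empty compound database")
    dq = atom_pair_descriptor(query)
    hits = []
    for comp_id in sorted(db):
        tc = descriptor_tanimoto(dq, atom_pair_descriptor(db[comp_id]))
        if tc >= tanimoto_min:
            hits.append((comp_id, tc))
    hits.sort(key=lambda x: (-x[1], x[0]))
    return hits
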