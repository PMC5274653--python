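"""Parse PDBx/mmCIF entries into the molecular data model.

An entry is decomposed into *unit molecules*: one molecule per non-water
``label_asym_id`` of the asymmetric unit, carrying its atoms, polymer
sequence and molecule type.  Residue numbering is mmCIF's canonical
``label_seq_id`` throughout, so the PDB files and FASTA sequences written
from this model always agree on residue numbers.  Assembly definitions
(``_pdbx_struct_assembly_gen``) and symmetry operators
(``_pdbx_struct_oper_list``) are retained verbatim for the assembly builder;
every declared biological-unit candidate is kept, since there is no reliable
standard for picking a single correct one.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from gemmi import cif

from .config import (
    METAL_ELEMENTS,
    NUCLEOTIDE_COMPS,
    STANDARD_AA,
    WATER_COMPS,
)


class MmcifParseError(ValueError):
    """Raised when a required mmCIF category is malformed or missing."""


class EmptyEntryError(ValueError):
    """Raised when an entry contains no non-water molecule."""


class PdbFormatOverflowError(ValueError):
    """Raised when a molecule cannot be written in the classical PDB format."""


@dataclasses.dataclass
class Atom:
    """One heavy or hydrogen atom with mmCIF-canonical residue numbering.

    ``seq_id`` is ``label_seq_id`` (1-based) for polymers and ``None`` for
    single-residue components such as ligands and metals.
    """

    atom_name: str
    element: str
    comp_id: str
    seq_id: Optional[int]
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclasses.dataclass
class UnitMol:
    """One non-water molecule of the asymmetric unit."""

    pdb_id: str
    asym_id: str
    mol_type: str  # protein | nucleotide | compound | metal | precipitant | other
    comp_id: Optional[str]  # set for single-component molecules only
    sequence: Optional[str]  # one-letter string for polymers
    pdbx_description: str
    atoms: list[Atom]
    cluster95: Optional[str] = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.pdb_id, self.asym_id)

    @property
    def is_polymer(self) -> bool:
        return self.mol_type in ("protein", "nucleotide")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms if a.is_heavy]
        return np.array(pts) if pts else np.zeros((0, 3))


@dataclasses.dataclass
class Operator:
    """A rigid rotation + translation used to build biological units."""

    oper_id: str
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-5):
            raise ValueError(f"operator {self.oper_id}: rotation not orthonormal")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation

    @classmethod
    def identity(cls, oper_id: str = "1") -> "Operator":
        return cls(oper_id, np.eye(3), np.zeros(3))


@dataclasses.dataclass
class AssemblyDef:
    """One declared biological-unit candidate.

    ``members`` pairs each asym_id with the (possibly composite) operator
    expression of its generator row, e.g. ``("A", "(1-3)")``.
    """

    pdb_id: str
    assembly_id: str
    members: list[tuple[str, str]]
    provenance: str = "author"  # author | software | both

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"assembly {self.assembly_id}: no members")


@dataclasses.dataclass
class Entry:
    """Container for one parsed mmCIF file."""

    pdb_id: str
    unitmols: list[UnitMol]
    operators: list[Operator]
    assemblies: list[AssemblyDef]

    def unitmol(self, asym_id: str) -> UnitMol:
        for u in self.unitmols:
            if u.asym_id == asym_id:
                return u
        raise KeyError(f"{self.pdb_id}: no unitmol with asym_id {asym_id!r}")

    def assembly(self, assembly_id: str) -> AssemblyDef:
        for a in self.assemblies:
            if a.assembly_id == assembly_id:
                return a
        raise KeyError(f"{self.pdb_id}: no assembly {assembly_id!r}")

    def operator(self, oper_id: str) -> Operator:
        for op in self.operators:
            if op.oper_id == oper_id:
                return op
        raise KeyError(f"{self.pdb_id}: operator {oper_id!r} not declared")


# ---------------------------------------------------------------------------
# parsing

_ATOM_SITE_TAGS = [
    "group_PDB", "label_atom_id", "type_symbol", "label_comp_id",
    "label_asym_id", "label_seq_id", "Cartn_x", "Cartn_y", "Cartn_z",
    "?occupancy", "?label_alt_id", "?pdbx_PDB_model_num",
]


def _as_str(v: str) -> str:
    return cif.as_string(v)


def classify_moltype(
    poly_kind: Optional[str],
    components: Sequence[str],
    n_atoms: int,
    elements: Sequence[str],
    precipitant_list: Iterable[str] = (),
) -> str:
    """Assign the interaction-class molecule type of one unit molecule.

    ``poly_kind`` is the entity_poly type when declared ("protein" /
    "nucleotide"), else None; ``components`` the distinct comp_ids.
    """
    precip = set(precipitant_list)
    if poly_kind == "protein":
        return "protein"
    if poly_kind == "nucleotide":
        return "nucleotide"
    comps = list(dict.fromkeys(components))
    if poly_kind is None and len(comps) > 1:
        # undeclared polymer: vote by component vocabulary
        n_aa = sum(c in STANDARD_AA for c in comps)
        n_nt = sum(c in NUCLEOTIDE_COMPS for c in comps)
        if n_aa >= n_nt and n_aa > len(comps) // 2:
            return "protein"
        if n_nt > len(comps) // 2:
            return "nucleotide"
        return "other"
    comp = comps[0] if comps else ""
    if n_atoms == 1 and len(elements) == 1 and elements[0].upper() in METAL_ELEMENTS:
        return "metal"
    if comp in precip:
        return "precipitant"
    if len(comps) == 1:
        return "compound"
    return "other"


def _poly_kind_of(entity_type: str) -> Optional[str]:
    t = entity_type.lower()
    if "polypeptide" in t:
        return "protein"
    if "nucleotide" in t or "ribonucleotide" in t:
        return "nucleotide"
    return None


def _one_letter(comp: str, kind: str) -> str:
    if kind == "protein":
        return STANDARD_AA.get(comp, "X")
    return NUCLEOTIDE_COMPS.get(comp, "X")


def parse_entry(
    source: str | Path,
    precipitant_list: Iterable[str] = (),
) -> Entry:
    """Parse one PDBx/mmCIF entry into an :class:`Entry`.

    ``source`` may be a path or the mmCIF text itself.  Waters never produce
    a UnitMol; only the first model of multi-model entries is read; for
    alternate locations the highest-occupancy one is kept.  When the file
    declares no assembly at all, a single identity assembly covering every
    molecule is synthesized so downstream stages always have a biological
    unit to work with.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        doc = cif.read_string(text)
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise MmcifParseError(f"cannot read mmCIF document: {exc}") from exc

    pdb_id = (block.find_value("_entry.id") or block.name or "xxxx").strip().lower()
    pdb_id = _as_str(pdb_id).lower()

    table = block.find("_atom_site.", _ATOM_SITE_TAGS)
    if len(table) == 0:
        raise MmcifParseError("category _atom_site missing or incomplete")

    # entity metadata
    descriptions: dict[str, str] = {}
    ent_table = block.find("_entity.", ["id", "?pdbx_description"])
    for row in ent_table:
        descriptions[_as_str(row[0])] = _as_str(row[1]) if row.has(1) else ""

    poly_kind_by_entity: dict[str, Optional[str]] = {}
    canon_seq_by_entity: dict[str, str] = {}
    for row in block.find("_entity_poly.", ["entity_id", "?type", "?pdbx_seq_one_letter_code_can"]):
        eid = _as_str(row[0])
        poly_kind_by_entity[eid] = _poly_kind_of(_as_str(row[1])) if row.has(1) else "protein"
        if row.has(2):
            canon_seq_by_entity[eid] = "".join(_as_str(row[2]).split())

    entity_of_asym: dict[str, str] = {}
    for row in block.find("_struct_asym.", ["id", "entity_id"]):
        entity_of_asym[_as_str(row[0])] = _as_str(row[1])

    # atoms, first model only, best-occupancy altloc
    per_asym: dict[str, dict[tuple, tuple[float, Atom]]] = {}
    first_model: Optional[str] = None
    for row in table:
        if row.has(11):
            model = row[11]
            if first_model is None:
                first_model = model
            elif model != first_model:
                continue
        comp = _as_str(row[3])
        if comp.upper() in WATER_COMPS:
            continue
        asym = _as_str(row[4])
        seq_raw = row[5]
        seq_id = None if cif.is_null(seq_raw) else int(seq_raw)
        try:
            xyz = (float(row[6]), float(row[7]), float(row[8]))
        except ValueError as exc:
            raise MmcifParseError(f"category _atom_site: bad coordinate ({exc})") from exc
        occ = float(row[9]) if row.has(9) and not cif.is_null(row[9]) else 1.0
        atom = Atom(
            atom_name=_as_str(row[1]),
            element=_as_str(row[2]),
            comp_id=comp,
            seq_id=seq_id,
            xyz=np.array(xyz),
        )
        key = (seq_id, comp, atom.atom_name)
        slot = per_asym.setdefault(asym, {})
        if key not in slot or occ > slot[key][0]:
            slot[key] = (occ, atom)

    if not per_asym:
        raise EmptyEntryError(f"{pdb_id}: no non-water molecules in _atom_site")

    precip = set(precipitant_list)
    unitmols: list[UnitMol] = []
    for asym in per_asym:
        atoms = [a for _, a in per_asym[asym].values()]
        eid = entity_of_asym.get(asym)
        poly_kind = poly_kind_by_entity.get(eid) if eid else None
        comps = [a.comp_id for a in atoms]
        elements = list(dict.fromkeys(a.element for a in atoms))
        mol_type = classify_moltype(poly_kind, comps, len(atoms), elements, precip)

        sequence = None
        comp_id: Optional[str] = None
        if mol_type in ("protein", "nucleotide"):
            seq_ids = [a.seq_id for a in atoms if a.seq_id is not None]
            n = max(seq_ids) if seq_ids else 0
            canon = canon_seq_by_entity.get(eid or "", "")
            if canon:
                sequence = canon if len(canon) >= n else canon + "X" * (n - len(canon))
            else:
                letters = ["X"] * n
                for a in atoms:
                    if a.seq_id is not None:
                        letters[a.seq_id - 1] = _one_letter(a.comp_id, mol_type)
                sequence = "".join(letters)
        else:
            distinct = list(dict.fromkeys(comps))
            if len(distinct) == 1:
                comp_id = distinct[0]
        unitmols.append(
            UnitMol(
                pdb_id=pdb_id,
                asym_id=asym,
                mol_type=mol_type,
                comp_id=comp_id,
                sequence=sequence,
                pdbx_description=descriptions.get(eid or "", ""),
                atoms=atoms,
            )
        )
    unitmols.sort(key=lambda u: u.asym_id)

    # symmetry operators
    operators: list[Operator] = []
    oper_tags = ["id"] + [f"matrix[{i}][{j}]" for i in (1, 2, 3) for j in (1, 2, 3)] \
        + [f"vector[{i}]" for i in (1, 2, 3)]
    for row in block.find("_pdbx_struct_oper_list.", oper_tags):
        try:
            mat = np.array([float(row[k]) for k in range(1, 10)]).reshape(3, 3)
            vec = np.array([float(row[k]) for k in range(10, 13)])
        except ValueError as exc:
            raise MmcifParseError(f"category _pdbx_struct_oper_list: {exc}") from exc
        operators.append(Operator(_as_str(row[0]), mat, vec))

    # assemblies
    provenance: dict[str, str] = {}
    for row in block.find("_pdbx_struct_assembly.", ["id", "?details"]):
        details = _as_str(row[1]).lower() if row.has(1) else ""
        has_auth = "author" in details
        has_soft = "software" in details
        provenance[_as_str(row[0])] = (
            "both" if has_auth and has_soft else "software" if has_soft else "author"
        )

    asym_ids_present = {u.asym_id for u in unitmols}
    members_by_assembly: dict[str, list[tuple[str, str]]] = {}
    for row in block.find("_pdbx_struct_assembly_gen.", ["assembly_id", "oper_expression", "asym_id_list"]):
        aid = _as_str(row[0])
        expr = _as_str(row[1])
        asyms = [s.strip() for s in _as_str(row[2]).split(",") if s.strip()]
        mem = members_by_assembly.setdefault(aid, [])
        for asym in asyms:
            if asym in asym_ids_present:  # water asym_ids silently dropped
                mem.append((asym, expr))

    assemblies = [
        AssemblyDef(pdb_id, aid, members, provenance.get(aid, "author"))
        for aid, members in members_by_assembly.items()
        if members
    ]
    if not assemblies:
        if not operators:
            operators.append(Operator.identity("1"))
        assemblies = [
            AssemblyDef(pdb_id, "1", [(u.asym_id, operators[0].oper_id) for u in unitmols])
        ]

    return Entry(pdb_id, unitmols, operators, assemblies)


# ---------------------------------------------------------------------------
# writers

def write_unitmol_pdb(u: UnitMol, atoms: Optional[Sequence[Atom]] = None,
                      chain_id: Optional[str] = None) -> str:
    """Render one molecule as classical PDB text.

    Residue numbers are label_seq_id (single-residue components get residue
    number 1), so they match the FASTA numbering exactly.
    """
    atoms = list(u.atoms if atoms is None else atoms)
    if not atoms:
        raise ValueError(f"{u.pdb_id}/{u.asym_id}: no atoms to write")
    if len(atoms) > 99999:
        raise PdbFormatOverflowError(
            f"{u.pdb_id}/{u.asym_id}: {len(atoms)} atoms exceed the classical PDB limit"
        )
    record = "ATOM" if u.is_polymer else "HETATM"
    chain = (chain_id or u.asym_id)[:1]
    lines = [f"REMARK 300 UNITMOL {u.pdb_id} {u.asym_id} {u.mol_type}"]
    for i, a in enumerate(atoms, start=1):
        name = a.atom_name
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        seq = a.seq_id if a.seq_id is not None else 1
        lines.append(
            f"{record:<6s}{i:5d} {name:<4.4s} {a.comp_id:>3.3s} {chain}"
            f"{seq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2.2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def fasta_id(u: UnitMol) -> str:
    return f"{u.pdb_id}_{u.asym_id}"


def parse_fasta_id(identifier: str) -> tuple[str, str]:
    """Invert :func:`fasta_id` (header codec round-trip)."""
    pdb_id, _, asym = identifier.partition("_")
    if not pdb_id or not asym:
        raise ValueError(f"not a pdbid_asym identifier: {identifier!r}")
    return pdb_id, asym


def export_fasta(unitmols: Iterable[UnitMol], width: int = 60) -> str:
    """FASTA text with one record per protein unit molecule."""
    records = []
    for u in unitmols:
        if u.mol_type != "protein" or not u.sequence:
            continue
        seq = "\n".join(u.sequence[i:i + width] for i in range(0, len(u.sequence), width))
        records.append(f">{fasta_id(u)}\n{seq}")
    if not records:
        warnings.warn("no protein unit molecules to export", stacklevel=2)
        return ""
    return "\n".join(records) + "\n"


def write_component_sdf(u: UnitMol) -> str:
    """SDF (V2000) text for a single-component molecule.

    Multi-residue molecules (peptides, oligosaccharides) are not written.
    Bonds are perceived from the 3D coordinates; when perception fails the
    connection table is left empty with a warning.
    """
    if u.comp_id is None:
        raise ValueError(f"{u.pdb_id}/{u.asym_id}: not a single-component molecule")
    from rdkit import Chem
    from rdkit.Chem import rdDetermineBonds
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    conf = Chem.Conformer(len(u.atoms))
    for i, a in enumerate(u.atoms):
        elem = a.element.capitalize()
        mol.AddAtom(Chem.Atom(elem))
        conf.SetAtomPosition(i, Point3D(*map(float, a.xyz)))
    mol.AddConformer(conf)
    m = mol.GetMol()
    try:
        rdDetermineBonds.DetermineConnectivity(m)
    except Exception:
        warnings.warn(f"{u.comp_id}: bond perception failed; writing atoms only",
                      stacklevel=2)
    m.SetProp("_Name", u.comp_id)
    return Chem.MolToMolBlock(m, kekulize=False)
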