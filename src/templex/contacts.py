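"""Residue-level contact detection and the four-table relational store.

Two molecules of the same biological unit are *in contact* when any pair of
their heavy atoms lies within the cutoff (4.0 Å by default).  The interface
is recorded residue-wise on both sides.  Contacts, molecules and assemblies
are persisted in a single-file SQLite database with four tables named
``unitmol``, ``asmblmol``, ``assembly`` and ``contact``; a contacting pair
that recurs in several biological-unit candidates is stored once with the
accumulated list of assembly ids.
"""

from __future__ import annotations

import dataclasses
import json
import sqlite3
from pathlib import Path
from typing import Iterable, Optional

from scipy.spatial import cKDTree

from .assembly import AsmblMol, build_assembly
from .mmcif_model import Entry, UnitMol


class SelfContactError(ValueError):
    """The same assembly molecule was passed as both sides of a contact."""


MolKey = tuple[str, str]  # (asym_id, oper_expression)


@dataclasses.dataclass
class Contact:
    """The residue-level interface between two assembly molecules.

    ``seq_ids_a``/``seq_ids_b`` are the sorted label_seq_id lists of residues
    of each side that touch the other side (single-residue components are
    residue 1).  The record is symmetric: swapping the two molecules swaps
    the residue lists.
    """

    pdb_id: str
    mol_a: MolKey
    mol_b: MolKey
    seq_ids_a: list[int]
    seq_ids_b: list[int]
    assembly_ids: list[str] = dataclasses.field(default_factory=list)

    def flipped(self) -> "Contact":
        return Contact(self.pdb_id, self.mol_b, self.mol_a,
                       list(self.seq_ids_b), list(self.seq_ids_a),
                       list(self.assembly_ids))

    @property
    def pair_key(self) -> tuple[str, MolKey, MolKey]:
        return (self.pdb_id, self.mol_a, self.mol_b)


def find_contact_residues(
    a: AsmblMol, b: AsmblMol, cutoff: float = 4.0
) -> Optional[Contact]:
    """Contact record for two assembly molecules, or None when apart.

    Hydrogen/deuterium atoms are ignored.  A KD-tree restricts the candidate
    pairs; the result is identical to the all-pairs distance scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if a is b or (a.pdb_id, a.asym_id, a.oper_expression) == (b.pdb_id, b.asym_id, b.oper_expression):
        raise SelfContactError(f"molecule {a.key} passed as both contact partners")
    heavy_a = a.heavy_atoms()
    heavy_b = b.heavy_atoms()
    if not heavy_a or not heavy_b:
        return None
    tree = cKDTree([at.xyz for at in heavy_b])
    res_a: set[int] = set()
    res_b: set[int] = set()
    for at in heavy_a:
        hits = tree.query_ball_point(at.xyz, r=cutoff)
        if hits:
            res_a.add(at.seq_id if at.seq_id is not None else 1)
            for j in hits:
                bj = heavy_b[j]
                res_b.add(bj.seq_id if bj.seq_id is not None else 1)
    if not res_a:
        return None
    return Contact(a.pdb_id, (a.asym_id, a.oper_expression),
                   (b.asym_id, b.oper_expression),
                   sorted(res_a), sorted(res_b))


def build_contact_table(
    assembly_mols: list[AsmblMol], assembly_id: str, cutoff: float = 4.0
) -> list[Contact]:
    """All contacting unordered pairs among the molecules of one assembly."""
    contacts = []
    for i in range(len(assembly_mols)):
        for j in range(i + 1, len(assembly_mols)):
            c = find_contact_residues(assembly_mols[i], assembly_mols[j], cutoff)
            if c is not None:
                c.assembly_ids = [assembly_id]
                contacts.append(c)
    return contacts


_SCHEMA = """
CREATE TABLE IF NOT EXISTS unitmol (
    pdb_id TEXT NOT NULL, asym_id TEXT NOT NULL,
    mol_type TEXT, comp_id TEXT, sequence TEXT,
    pdbx_description TEXT, cluster95 TEXT,
    PRIMARY KEY (pdb_id, asym_id));
CREATE TABLE IF NOT EXISTS asmblmol (
    pdb_id TEXT NOT NULL, asym_id TEXT NOT NULL, oper_expression TEXT NOT NULL,
    assembly_ids TEXT,
    PRIMARY KEY (pdb_id, asym_id, oper_expression));
CREATE TABLE IF NOT EXISTS assembly (
    pdb_id TEXT NOT NULL, assembly_id TEXT NOT NULL,
    provenance TEXT, asym_ids TEXT, oper_expressions TEXT,
    PRIMARY KEY (pdb_id, assembly_id));
CREATE TABLE IF NOT EXISTS contact (
    pdb_id TEXT NOT NULL,
    asym_id TEXT NOT NULL, oper_expression TEXT NOT NULL,
    asym_id_con TEXT NOT NULL, oper_expression_con TEXT NOT NULL,
    seq_ids TEXT, seq_ids_con TEXT, assembly_ids TEXT,
    PRIMARY KEY (pdb_id, asym_id, oper_expression, asym_id_con, oper_expression_con));
"""


class ContactStore:
    """SQLite-backed store of unit molecules, assemblies and contacts.

    Entries added in-session are also kept in memory so that modeling
    operations can reach their coordinates without re-reading files.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.con = sqlite3.connect(self.path)
        self.con.executescript(_SCHEMA)
        self.entries: dict[str, Entry] = {}

    def close(self) -> None:
        self.con.close()

    # -- building -----------------------------------------------------------

    def add_entry(self, entry: Entry, cutoff: float = 4.0) -> dict:
        """Ingest one parsed entry: molecules, assemblies, contacts.

        Returns per-entry counts for logging.
        """
        cur = self.con.cursor()
        for u in entry.unitmols:
            cur.execute(
                "INSERT OR REPLACE INTO unitmol VALUES (?,?,?,?,?,?,?)",
                (u.pdb_id, u.asym_id, u.mol_type, u.comp_id, u.sequence,
                 u.pdbx_description, u.cluster95),
            )
        asmbl_assemblies: dict[tuple[str, str], list[str]] = {}
        merged: dict[tuple, Contact] = {}
        n_asmblmols = 0
        for adef in entry.assemblies:
            mols = build_assembly(entry, adef.assembly_id)
            n_asmblmols += len(mols)
            cur.execute(
                "INSERT OR REPLACE INTO assembly VALUES (?,?,?,?,?)",
                (entry.pdb_id, adef.assembly_id, adef.provenance,
                 json.dumps([m[0] for m in adef.members]),
                 json.dumps([m[1] for m in adef.members])),
            )
            for m in mols:
                asmbl_assemblies.setdefault((m.asym_id, m.oper_expression), []).append(
                    adef.assembly_id
                )
            for c in build_contact_table(mols, adef.assembly_id, cutoff):
                if c.mol_b < c.mol_a:
                    c = c.flipped()
                key = (c.mol_a, c.mol_b)
                if key in merged:
                    merged[key].assembly_ids.extend(c.assembly_ids)
                else:
                    merged[key] = c
        for (asym, oper), aids in asmbl_assemblies.items():
            cur.execute(
                "INSERT OR REPLACE INTO asmblmol VALUES (?,?,?,?)",
                (entry.pdb_id, asym, oper, json.dumps(sorted(set(aids)))),
            )
        for c in merged.values():
            cur.execute(
                "INSERT OR REPLACE INTO contact VALUES (?,?,?,?,?,?,?,?)",
                (c.pdb_id, c.mol_a[0], c.mol_a[1], c.mol_b[0], c.mol_b[1],
                 json.dumps(c.seq_ids_a), json.dumps(c.seq_ids_b),
                 json.dumps(sorted(set(c.assembly_ids)))),
            )
        self.con.commit()
        self.entries[entry.pdb_id] = entry
        return {
            "pdb_id": entry.pdb_id,
            "unitmols": len(entry.unitmols),
            "assemblies": len(entry.assemblies),
            "asmblmols": n_asmblmols,
            "contacts": len(merged),
        }

    def assign_cluster95(self, identity_min: float = 95.0,
                         coverage_min: float = 80.0) -> dict[str, str]:
        """Cluster all protein sequences and write cluster95 labels back."""
        from .seqsearch import cluster95 as _cluster95

        seqs = self.protein_sequences()
        labels = _cluster95(seqs, identity_min=identity_min,
                            coverage_min=coverage_min)
        cur = self.con.cursor()
        for sid, label in labels.items():
            pdb_id, _, asym = sid.partition("_")
            cur.execute(
                "UPDATE unitmol SET cluster95=? WHERE pdb_id=? AND asym_id=?",
                (label, pdb_id, asym),
            )
        self.con.commit()
        for entry in self.entries.values():
            for u in entry.unitmols:
                u.cluster95 = labels.get(f"{u.pdb_id}_{u.asym_id}", u.cluster95)
        return labels

    # -- retrieval ----------------------------------------------------------

    def _unitmol_from_row(self, row: tuple) -> UnitMol:
        return UnitMol(pdb_id=row[0], asym_id=row[1], mol_type=row[2],
                       comp_id=row[3], sequence=row[4], pdbx_description=row[5],
                       atoms=[], cluster95=row[6])

    def unitmol_meta(self, pdb_id: str, asym_id: str) -> UnitMol:
        row = self.con.execute(
            "SELECT * FROM unitmol WHERE pdb_id=? AND asym_id=?",
            (pdb_id, asym_id)).fetchone()
        if row is None:
            raise KeyError(f"unitmol ({pdb_id}, {asym_id}) not in store")
        return self._unitmol_from_row(row)

    def all_unitmols(self) -> list[UnitMol]:
        rows = self.con.execute(
            "SELECT * FROM unitmol ORDER BY pdb_id, asym_id").fetchall()
        return [self._unitmol_from_row(r) for r in rows]

    def protein_sequences(self) -> dict[str, str]:
        rows = self.con.execute(
            "SELECT pdb_id, asym_id, sequence FROM unitmol "
            "WHERE mol_type='protein' AND sequence IS NOT NULL "
            "ORDER BY pdb_id, asym_id").fetchall()
        return {f"{p}_{a}": s for p, a, s in rows}

    def unitmols_with_comp(self, comp_id: str) -> list[MolKey]:
        rows = self.con.execute(
            "SELECT pdb_id, asym_id FROM unitmol WHERE comp_id=? "
            "ORDER BY pdb_id, asym_id", (comp_id,)).fetchall()
        return [tuple(r) for r in rows]

    def compound_comp_ids(self) -> list[str]:
        rows = self.con.execute(
            "SELECT DISTINCT comp_id FROM unitmol WHERE comp_id IS NOT NULL "
            "AND mol_type IN ('compound','metal','precipitant') ORDER BY comp_id"
        ).fetchall()
        return [r[0] for r in rows]

    def _contact_from_row(self, row: tuple) -> Contact:
        return Contact(row[0], (row[1], row[2]), (row[3], row[4]),
                       json.loads(row[5]), json.loads(row[6]),
                       json.loads(row[7]))

    def all_contacts(self) -> list[Contact]:
        rows = self.con.execute("SELECT * FROM contact ORDER BY "
                                "pdb_id, asym_id, oper_expression, "
                                "asym_id_con, oper_expression_con").fetchall()
        return [self._contact_from_row(r) for r in rows]

    def query_contacts(self, pdb_id: str, asym_id: str) -> list[tuple[UnitMol, Contact]]:
        """All contact partners of a unit molecule over all its operators.

        Each result is oriented so that ``mol_a`` is the queried molecule;
        the partner's unitmol metadata (type, comp_id, description,
        cluster95) is joined in.
        """
        # validate the key first
        self.unitmol_meta(pdb_id, asym_id)
        out: list[tuple[UnitMol, Contact]] = []
        rows = self.con.execute(
            "SELECT * FROM contact WHERE pdb_id=? AND (asym_id=? OR asym_id_con=?) "
            "ORDER BY asym_id, oper_expression, asym_id_con, oper_expression_con",
            (pdb_id, asym_id, asym_id)).fetchall()
        for row in rows:
            c = self._contact_from_row(row)
            if c.mol_a[0] != asym_id:
                c = c.flipped()
            out.append((self.unitmol_meta(pdb_id, c.mol_b[0]), c))
        return out

    def assemblies_of(self, pdb_id: str) -> list[str]:
        rows = self.con.execute(
            "SELECT assembly_id FROM assembly WHERE pdb_id=? ORDER BY assembly_id",
            (pdb_id,)).fetchall()
        return [r[0] for r in rows]

    def entry(self, pdb_id: str) -> Entry:
        try:
            return self.entries[pdb_id]
        except KeyError:
            raise KeyError(
                f"coordinates for entry {pdb_id!r} are not loaded in this session"
            ) from None


def build_database(
    entries: Iterable[Entry], path: str | Path = ":memory:",
    cutoff: float = 4.0, cluster: bool = True,
) -> tuple[ContactStore, list[dict]]:
    """Build a contact database from parsed entries; returns (store, logs)."""
    store = ContactStore(path)
    logs = [store.add_entry(e, cutoff=cutoff) for e in entries]
    if cluster:
        store.assign_cluster95()
    return store, logs
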