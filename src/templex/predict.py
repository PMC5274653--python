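"""The search services: contact prediction and multimer template discovery.

Given a query protein, its homologs in the structure database are found and
every molecule contacting a homolog (in any biological-unit candidate)
becomes a *predicted contact molecule* of the query, with the template's
interface residues mapped through the alignment onto query positions.
Predictions fall into seven interaction classes — hetero oligomer, homo
oligomer, nucleotide complex, other-polymer complex, small-compound
complex, metal complex and precipitant complex — where "same protein" is
membership in the same cluster95 sequence cluster.

Because well-studied families yield hundreds of redundant predictions, two
reduction rules are applied: predicted complexes of one class are
single-linkage clustered (link when the contact-molecule *type key* is
identical and the binding-site Tanimoto exceeds 0.2) and shown through one
representative; monomer templates are kept greedily in E-value order only
when they align more than 10 query residues not covered before.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional

import networkx as nx

from .chem import CompoundGraph, search_similar_compounds
from .contacts import Contact, ContactStore
from .mmcif_model import UnitMol, fasta_id
from .seqsearch import Alignment, SeqDB, contact_site_identity, search_homologs

INTERACTION_CLASSES = (
    "hetero_oligomer", "homo_oligomer", "nucleotide", "other_polymer",
    "compound", "metal", "precipitant",
)


@dataclasses.dataclass
class PredictionRecord:
    """One (query, template complex, contact molecule) prediction."""

    query_id: str
    template_assembly: tuple[str, str]  # (pdb_id, first assembly_id)
    homolog_mol: tuple[str, str]  # (asym_id, oper_expression)
    contact_mol: tuple[str, str]
    contact_meta: UnitMol
    aln: Alignment
    interaction_class: str
    contact_sites_on_query: list[int]
    contact_type_key: str
    mappable: bool = True  # False when no template contact site is aligned


@dataclasses.dataclass
class SiteSummary:
    """Aggregated contact information for one query sequence position."""

    query_pos: int
    query_aa: str
    contacting_molecule_types: Counter
    best_template: Optional[tuple[str, str, float]]  # (pdb_id, asym_id, identity_all)


def classify_interaction(homolog: UnitMol, partner: UnitMol) -> str:
    """Interaction class of a (homolog, contact molecule) pair."""
    t = partner.mol_type
    if t == "protein":
        same = (homolog.cluster95 is not None
                and homolog.cluster95 == partner.cluster95)
        return "homo_oligomer" if same else "hetero_oligomer"
    if t == "nucleotide":
        return "nucleotide"
    if t in ("compound", "metal", "precipitant"):
        return t
    return "other_polymer"


def contact_type_key(partner: UnitMol) -> str:
    """The redundancy key of a contact molecule.

    cluster95 for proteins; comp_id for compounds, metals and precipitants;
    the sequence for nucleotides; pdbx_description for anything else.
    """
    if partner.mol_type == "protein":
        return partner.cluster95 or fasta_id(partner)
    if partner.mol_type in ("compound", "metal", "precipitant"):
        return partner.comp_id or ""
    if partner.mol_type == "nucleotide":
        return partner.sequence or ""
    return partner.pdbx_description


def binding_site_tanimoto(sites_a: set[int], sites_b: set[int]) -> float:
    """|A∩B| / |A∪B| over query-position sets; 0 when the union is empty."""
    union = set(sites_a) | set(sites_b)
    if not union:
        return 0.0
    return len(set(sites_a) & set(sites_b)) / len(union)


def predict_contacts_for_protein(
    query_seq: str,
    store: ContactStore,
    db: Optional[SeqDB] = None,
    evalue_max: float = 1e-4,
    min_identity_pct: float = 0.0,
    backend: str = "auto",
    query_id: str = "query",
) -> list[PredictionRecord]:
    """Predicted contact molecules of a query protein sequence.

    One record per (homolog alignment, contact partner) over all biological
    units; records whose template contact sites all fall outside the aligned
    region are kept but flagged unmappable so a full listing stays faithful.
    """
    if db is None:
        db = SeqDB(store.protein_sequences())
    alignments = search_homologs(query_seq, db, evalue_max=evalue_max,
                                 min_identity_pct=min_identity_pct,
                                 backend=backend, query_id=query_id)
    records: list[PredictionRecord] = []
    for aln in alignments:
        pdb_id, asym = aln.template_id
        homolog_meta = store.unitmol_meta(pdb_id, asym)
        for partner_meta, contact in store.query_contacts(pdb_id, asym):
            rec_aln = dataclasses.replace(aln)
            contact_site_identity(rec_aln, contact.seq_ids_a)
            t2q = rec_aln.template_to_query()
            sites = sorted(t2q[t] for t in contact.seq_ids_a if t in t2q)
            records.append(PredictionRecord(
                query_id=query_id,
                template_assembly=(pdb_id, contact.assembly_ids[0]
                                   if contact.assembly_ids else "1"),
                homolog_mol=contact.mol_a,
                contact_mol=contact.mol_b,
                contact_meta=partner_meta,
                aln=rec_aln,
                interaction_class=classify_interaction(homolog_meta, partner_meta),
                contact_sites_on_query=sites,
                contact_type_key=contact_type_key(partner_meta),
                mappable=bool(sites),
            ))
    return records


def _rep_sort_key(rec: PredictionRecord):
    ident = rec.aln.identity_contact
    return (rec.aln.evalue,
            -(ident if ident is not None else -1.0),
            rec.aln.template_id, rec.homolog_mol, rec.contact_mol)


def cluster_representatives(
    records: list[PredictionRecord],
    site_tanimoto_min: float = 0.2,
) -> list[tuple[list[PredictionRecord], PredictionRecord]]:
    """Single-linkage redundancy clusters with one representative each.

    Records of the same interaction class are linked when (1) their contact
    type keys are identical and (2) the Tanimoto coefficient of their
    query-mapped binding sites exceeds ``site_tanimoto_min``.  The
    representative has the lowest E-value (ties: higher contact-site
    identity, then lexicographic template id).
    """
    clusters: list[tuple[list[PredictionRecord], PredictionRecord]] = []
    by_class: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec.interaction_class, []).append(i)
    for cls in sorted(by_class):
        idxs = by_class[cls]
        g = nx.Graph()
        g.add_nodes_from(idxs)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if records[i].contact_type_key != records[j].contact_type_key:
                    continue
                tc = binding_site_tanimoto(set(records[i].contact_sites_on_query),
                                           set(records[j].contact_sites_on_query))
                if tc > site_tanimoto_min:
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            members = [records[i] for i in sorted(comp)]
            rep = min(members, key=_rep_sort_key)
            clusters.append((members, rep))
    clusters.sort(key=lambda c: _rep_sort_key(c[1]))
    return clusters


def select_monomer_representatives(
    alignments: list[Alignment], min_new_residues: int = 10
) -> list[Alignment]:
    """Greedy monomer-template selection in increasing E-value order.

    An alignment is kept iff it aligns strictly more than
    ``min_new_residues`` query positions not aligned by any previously kept
    alignment.
    """
    kept: list[Alignment] = []
    covered: set[int] = set()
    for aln in sorted(alignments, key=lambda a: (a.evalue, a.template_id)):
        new = aln.aligned_query_positions() - covered
        if not kept or len(new) > min_new_residues:
            kept.append(aln)
            covered |= aln.aligned_query_positions()
    return kept


def build_site_table(
    query_seq: str, records: list[PredictionRecord]
) -> list[SiteSummary]:
    """One row per query position aggregating all predictions touching it."""
    rows = []
    for pos in range(1, len(query_seq) + 1):
        types: Counter = Counter()
        best: Optional[tuple[str, str, float]] = None
        for rec in records:
            if pos in rec.contact_sites_on_query:
                types[rec.contact_type_key] += 1
            if pos in rec.aln.aligned_query_positions():
                cand = (rec.aln.template_id[0], rec.aln.template_id[1],
                        rec.aln.identity_all)
                if best is None or cand[2] > best[2] or \
                        (cand[2] == best[2] and cand[:2] < best[:2]):
                    best = cand
        rows.append(SiteSummary(pos, query_seq[pos - 1], types, best))
    return rows


@dataclasses.dataclass
class CompoundPrediction:
    """Proteins predicted to bind a query compound via one similar compound."""

    comp_id: str
    tanimoto: float
    proteins: list[tuple[UnitMol, Contact]]


def predict_proteins_for_compound(
    query: CompoundGraph,
    store: ContactStore,
    compound_db: dict[str, CompoundGraph],
    tanimoto_min: float = 0.7,
) -> list[CompoundPrediction]:
    """Predicted contacting proteins of a query compound.

    Database compounds similar to the query (descriptor Tanimoto ≥
    ``tanimoto_min``) are joined against the contact table; the proteins
    touching each similar compound are reported grouped per compound.
    """
    out: list[CompoundPrediction] = []
    for comp_id, tc in search_similar_compounds(query, compound_db, tanimoto_min):
        proteins: list[tuple[UnitMol, Contact]] = []
        for pdb_id, asym in store.unitmols_with_comp(comp_id):
            for partner_meta, contact in store.query_contacts(pdb_id, asym):
                if partner_meta.mol_type == "protein":
                    proteins.append((partner_meta, contact))
        out.append(CompoundPrediction(comp_id, tc, proteins))
    return out


@dataclasses.dataclass
class MultimerTemplate:
    """A template complex in which both query proteins have homologs."""

    pdb_id: str
    assembly_ids: list[str]
    aln_a: Alignment
    aln_b: Alignment
    contact: Contact  # oriented: mol_a is aln_a's chain, mol_b is aln_b's


def find_multimer_templates(
    query_a_seq: str,
    query_b_seq: Optional[str],
    store: ContactStore,
    db: Optional[SeqDB] = None,
    evalue_max: float = 1e-4,
    min_identity_pct: float = 0.0,
    backend: str = "auto",
) -> list[MultimerTemplate]:
    """Template complexes for a homo- (one query) or hetero-multimer (two).

    A template is a contacting pair of protein assembly molecules in some
    biological unit such that one side is homologous to query A and the
    other to query B.  Homo mode (``query_b_seq`` None) uses the same
    homolog list on both sides and includes same-unitmol pairs under
    different operators; hetero mode requires the two template chains to
    belong to different cluster95 clusters.
    """
    if db is None:
        db = SeqDB(store.protein_sequences())
    alns_a = search_homologs(query_a_seq, db, evalue_max=evalue_max,
                             min_identity_pct=min_identity_pct,
                             backend=backend, query_id="queryA")
    homo = query_b_seq is None
    alns_b = alns_a if homo else search_homologs(
        query_b_seq, db, evalue_max=evalue_max,
        min_identity_pct=min_identity_pct, backend=backend, query_id="queryB")
    map_a = {a.template_id: a for a in alns_a}
    map_b = {b.template_id: b for b in alns_b}

    results: list[MultimerTemplate] = []
    for contact in store.all_contacts():
        pdb_id = contact.pdb_id
        meta_a = store.unitmol_meta(pdb_id, contact.mol_a[0])
        meta_b = store.unitmol_meta(pdb_id, contact.mol_b[0])
        if meta_a.mol_type != "protein" or meta_b.mol_type != "protein":
            continue
        orientations = [(contact, meta_a, meta_b)]
        if not homo:
            orientations.append((contact.flipped(), meta_b, meta_a))
        for c, ma, mb in orientations:
            aln_a = map_a.get((pdb_id, c.mol_a[0]))
            aln_b = map_b.get((pdb_id, c.mol_b[0]))
            if aln_a is None or aln_b is None:
                continue
            if not homo and ma.cluster95 is not None and \
                    ma.cluster95 == mb.cluster95:
                continue  # hetero mode requires two distinct proteins
            ra = dataclasses.replace(aln_a)
            rb = dataclasses.replace(aln_b)
            contact_site_identity(ra, c.seq_ids_a)
            contact_site_identity(rb, c.seq_ids_b)
            results.append(MultimerTemplate(pdb_id, list(c.assembly_ids),
                                            ra, rb, c))
    results.sort(key=lambda t: (t.aln_a.evalue + t.aln_b.evalue, t.pdb_id,
                                t.contact.mol_a, t.contact.mol_b))
    return results
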