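"""Protein homolog search, redundancy clustering and contact-site identity.

Homologs are found by blastp-style local alignment against the FASTA
collection of all protein unit molecules, keeping hits with E-value below
1e-4 (optionally also above a user identity threshold).  Two backends share
one contract: the ``internal`` backend is a Smith–Waterman search
(BLOSUM62, gap open −11 / extend −1) with Karlin–Altschul E-values and runs
with no external binary; the ``blastp`` backend shells out to NCBI blastp
when available.

Redundancy among database sequences is captured by ``cluster95``:
single-linkage clusters of pairs with ≥95 % identity and ≥80 % aligned
coverage, defining the "same protein" relation used by the interaction
classifier.

The *contact-site identity* — the percentage of aligned template interface
residues whose query amino acid is identical — is the quality measure
attached to every predicted complex, reported alongside the overall
alignment identity.
"""

from __future__ import annotations

import dataclasses
import math
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .mmcif_model import UnitMol, fasta_id

# Karlin-Altschul parameters for gapped BLOSUM62 (-11/-1), as used by blastp.
_KA_LAMBDA = 0.267
_KA_K = 0.041

_AA_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


class EmptyDatabaseError(ValueError):
    pass


class SequenceValidationError(ValueError):
    pass


@dataclasses.dataclass
class Alignment:
    """A scored query↔template residue correspondence.

    ``pairs`` holds 1-based (query_pos, template_pos) aligned positions,
    strictly increasing in both coordinates.  Identities are percentages;
    ``identity_contact`` stays None until scored against a template contact
    record (and is None when no contact site is aligned).
    """

    query_id: str
    template_id: tuple[str, str]
    pairs: list[tuple[int, int]]
    score: float
    evalue: float
    identity_all: float
    coverage_query: float
    coverage_template: float
    query_seq: str
    template_seq: str
    identity_contact: Optional[float] = None

    def template_to_query(self) -> dict[int, int]:
        return {t: q for q, t in self.pairs}

    def aligned_query_positions(self) -> set[int]:
        return {q for q, _ in self.pairs}


@dataclasses.dataclass
class SeqDB:
    """FASTA collection of protein unit-molecule sequences.

    Identifiers are ``pdbid_asym`` and round-trip to (pdb_id, asym_id).
    """

    sequences: dict[str, str]

    @classmethod
    def from_unitmols(cls, unitmols: Iterable[UnitMol]) -> "SeqDB":
        return cls({fasta_id(u): u.sequence for u in unitmols
                    if u.mol_type == "protein" and u.sequence})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SeqDB":
        from Bio import SeqIO
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in sorted(self.sequences.items()):
                fh.write(f">{sid}\n{seq}\n")

    def __len__(self) -> int:
        return len(self.sequences)


def _validate_protein(seq: str, what: str = "query") -> str:
    seq = seq.strip().upper()
    bad = set(seq) - _AA_ALPHABET - {"U", "O", "J"}
    if bad:
        raise SequenceValidationError(
            f"{what} contains non-amino-acid characters: {sorted(bad)}")
    return seq


def _sanitize(seq: str) -> str:
    """Map rare letters outside the BLOSUM62 alphabet to X."""
    return "".join(c if c in _AA_ALPHABET else "X" for c in seq.upper())


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _align_pair(query: str, subject: str) -> tuple[float, list[tuple[int, int]]]:
    """Best local alignment; returns (raw score, 1-based aligned pairs)."""
    aligner = _make_aligner()
    q, s = _sanitize(query), _sanitize(subject)
    score = aligner.score(q, s)
    if score <= 0:
        return 0.0, []
    aln = aligner.align(q, s)[0]
    qblocks, sblocks = aln.aligned
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        pairs.extend((qi + 1, si + 1) for qi, si in zip(range(qs, qe), range(ss, se)))
    return float(score), pairs


def _identity_over_pairs(query: str, subject: str,
                         pairs: list[tuple[int, int]]) -> float:
    if not pairs:
        return 0.0
    same = sum(1 for q, s in pairs if query[q - 1].upper() == subject[s - 1].upper())
    return 100.0 * same / len(pairs)


def _evalue(score: float, m: int, total_db_len: int) -> float:
    return _KA_K * m * total_db_len * math.exp(-_KA_LAMBDA * score)


def search_homologs(
    query_seq: str,
    db: SeqDB,
    evalue_max: float = 1e-4,
    min_identity_pct: float = 0.0,
    backend: str = "auto",
    query_id: str = "query",
) -> list[Alignment]:
    """Find database homologs of a query protein sequence.

    Hits are local alignments with E-value < ``evalue_max`` and overall
    identity ≥ ``min_identity_pct``, sorted by increasing E-value.
    """
    query_seq = _validate_protein(query_seq)
    if len(query_seq) < 10:
        raise SequenceValidationError("query shorter than 10 residues")
    if len(db) == 0:
        raise EmptyDatabaseError("sequence database is empty")
    if backend == "auto":
        backend = "blastp" if shutil.which("blastp") and shutil.which("makeblastdb") \
            else "internal"
    if backend == "internal":
        hits = _search_internal(query_seq, db, query_id)
    elif backend == "blastp":
        hits = _search_blastp(query_seq, db, query_id, evalue_max)
    else:
        raise ValueError(f"unknown search backend {backend!r}")
    hits = [a for a in hits
            if a.evalue < evalue_max and a.identity_all >= min_identity_pct]
    hits.sort(key=lambda a: (a.evalue, -a.identity_all, a.template_id))
    return hits


def _make_alignment(query_id: str, query_seq: str, sid: str, subject: str,
                    score: float, pairs: list[tuple[int, int]],
                    evalue: float) -> Alignment:
    from .mmcif_model import parse_fasta_id
    return Alignment(
        query_id=query_id,
        template_id=parse_fasta_id(sid),
        pairs=pairs,
        score=score,
        evalue=evalue,
        identity_all=_identity_over_pairs(query_seq, subject, pairs),
        coverage_query=100.0 * len({q for q, _ in pairs}) / len(query_seq),
        coverage_template=100.0 * len({s for _, s in pairs}) / max(1, len(subject)),
        query_seq=query_seq,
        template_seq=subject,
    )


def _search_internal(query_seq: str, db: SeqDB, query_id: str) -> list[Alignment]:
    total = sum(len(s) for s in db.sequences.values())
    out = []
    for sid, subject in sorted(db.sequences.items()):
        score, pairs = _align_pair(query_seq, subject)
        if not pairs:
            continue
        out.append(_make_alignment(query_id, query_seq, sid, subject, score,
                                   pairs, _evalue(score, len(query_seq), total)))
    return out


def _search_blastp(query_seq: str, db: SeqDB, query_id: str,
                   evalue_max: float) -> list[Alignment]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db.write_fasta(tmp / "db.fasta")
        (tmp / "query.fasta").write_text(f">{query_id}\n{query_seq}\n")
        subprocess.run(
            ["makeblastdb", "-in", "db.fasta", "-dbtype", "prot"],
            cwd=tmp, check=True, capture_output=True)
        res = subprocess.run(
            ["blastp", "-query", "query.fasta", "-db", "db.fasta",
             "-evalue", str(max(evalue_max, 1e-200)),
             "-outfmt", "6 sseqid evalue score qseq sseq qstart sstart",
             "-max_target_seqs", "500"],
            cwd=tmp, check=True, capture_output=True, text=True)
    out, seen = [], set()
    for line in res.stdout.splitlines():
        sid, ev, score, qseq, sseq, qstart, sstart = line.split("\t")
        if sid in seen:  # keep best HSP per subject only
            continue
        seen.add(sid)
        qi, si = int(qstart), int(sstart)
        pairs = []
        for qc, sc in zip(qseq, sseq):
            if qc != "-" and sc != "-":
                pairs.append((qi, si))
            if qc != "-":
                qi += 1
            if sc != "-":
                si += 1
        out.append(_make_alignment(query_id, query_seq, sid,
                                   db.sequences[sid], float(score), pairs,
                                   float(ev)))
    return out


# ---------------------------------------------------------------------------
# cluster95

def cluster95(
    seqs: dict[str, str],
    identity_min: float = 95.0,
    coverage_min: float = 80.0,
) -> dict[str, str]:
    """Single-linkage clustering of sequences by identity and coverage.

    Two sequences are linked when their local alignment has identity ≥
    ``identity_min`` % and covers ≥ ``coverage_min`` % of the shorter
    sequence.  Connected components are clusters; the label is the
    lexicographically smallest member id, so the partition is invariant
    under input order.
    """
    g = nx.Graph()
    g.add_nodes_from(seqs)
    ids = sorted(seqs)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            _, pairs = _align_pair(seqs[a], seqs[b])
            if not pairs:
                continue
            ident = _identity_over_pairs(seqs[a], seqs[b], pairs)
            cover = 100.0 * len(pairs) / min(len(seqs[a]), len(seqs[b]))
            if ident >= identity_min and cover >= coverage_min:
                g.add_edge(a, b)
    labels: dict[str, str] = {}
    for comp in nx.connected_components(g):
        label = min(comp)
        for sid in comp:
            labels[sid] = label
    return labels


# ---------------------------------------------------------------------------
# contact-site identity

def contact_site_identity(
    aln: Alignment, template_contact_seq_ids: list[int]
) -> Optional[float]:
    """Identity (%) over the template's aligned contact positions.

    Contact positions outside the aligned region are excluded from the
    denominator; returns None when no contact position is aligned (and
    records the result on ``aln.identity_contact`` either way).
    """
    if not template_contact_seq_ids:
        raise ValueError("empty template contact-site list")
    t2q = aln.template_to_query()
    aligned = [t for t in template_contact_seq_ids if t in t2q]
    if not aligned:
        aln.identity_contact = None
        return None
    same = sum(
        1 for t in aligned
        if aln.query_seq[t2q[t] - 1].upper() == aln.template_seq[t - 1].upper()
    )
    aln.identity_contact = 100.0 * same / len(aligned)
    return aln.identity_contact
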