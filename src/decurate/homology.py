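"""Protein similarity search and the contig classification cascade.

Searches are exhaustive Smith-Waterman at desk scale (BLOSUM62, gap open
11 / extend 1) with Karlin-Altschul E-values using the standard gapped
constants.  An optional k-mer prefilter skips subject sequences sharing
fewer than two 4-mers with the query; it is off by default and enabled by
the pipeline for larger runs.

The cascade classifies a contig as

1. ``annotated`` — an ORF candidate has a confident hit in the reference
   protein database (the ORF is fixed by the hit);
2. ``conserved_uncharacterised`` — otherwise, a candidate has a confident
   hit in at least one comparator-species ORF database (a putative
   lineage-specific gene);
3. ``no_orf`` — otherwise; a strict cross-check against a prior assembly
   of the same organism records whether the contig was independently
   assembled before (supporting evidence that it is a real transcript).

A confident match requires E <= 1e-3 (inclusive) plus identity and
query-coverage floors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import exp

import edlib
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

from .orfs import OrfRecord, find_orfs

# standard gapped BLOSUM62/11/1 Karlin-Altschul constants
LAMBDA = 0.267
K_PARAM = 0.041

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()
_BLOSUM_ALPHABET = set(str(_ALIGNER.substitution_matrix.alphabet))


def _sanitize(aa: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X."""
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in aa.upper())


@dataclass
class Alignment:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    identity: float  # matches / aligned columns
    query_cov: float  # aligned query residues / query length
    subject_cov: float

    def __post_init__(self) -> None:
        assert 0 <= self.identity <= 1 and 0 <= self.query_cov <= 1


def evalue(score: float, query_len: int, db_len: int, lam: float = LAMBDA, k: float = K_PARAM) -> float:
    """Karlin-Altschul expected hit count E = K*m*n*exp(-lambda*score)."""
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return k * query_len * db_len * exp(-lam * score)


def local_align(
    query: str, subject: str, query_id: str = "query", subject_id: str = "subject"
) -> Alignment | None:
    """Optimal local alignment; None when no positive-scoring alignment exists."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q, s = _sanitize(query), _sanitize(subject)
    score = _ALIGNER.score(q, s)
    if score <= 0:
        return None
    aln = next(iter(_ALIGNER.align(q, s)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    q_blocks, s_blocks = aln.aligned
    q_res = int(sum(e - b for b, e in q_blocks))
    s_res = int(sum(e - b for b, e in s_blocks))
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        evalue=float("nan"),  # filled by search(), which knows the db size
        identity=counts.identities / columns if columns else 0.0,
        query_cov=q_res / len(q),
        subject_cov=s_res / len(s),
    )


def _shared_kmers(a: str, b: str, k: int = 4) -> int:
    words_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    return sum(1 for j in range(len(b) - k + 1) if b[j : j + k] in words_a)


def search(
    query: str,
    db: dict[str, str],
    query_id: str = "query",
    min_evalue: float = 1e-3,
    prefilter: bool = False,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 2,
) -> list[Alignment]:
    """All subjects with E <= ``min_evalue`` (inclusive), best first.

    Ranked by ascending E, then descending score, then subject id, so
    results are deterministic and independent of database record order.
    """
    if not db:
        raise ValueError("database is empty")
    db_len = sum(len(s) for s in db.values())
    hits = []
    q = _sanitize(query)
    for sid in sorted(db):
        subject = db[sid]
        if prefilter and _shared_kmers(q, _sanitize(subject), prefilter_k) < prefilter_min_shared:
            continue
        aln = local_align(q, subject, query_id, sid)
        if aln is None:
            continue
        aln.evalue = evalue(aln.score, len(q), db_len)
        if aln.evalue <= min_evalue:
            hits.append(aln)
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id))
    return hits


def is_confident(
    match: Alignment,
    min_identity: float = 0.35,
    min_query_cov: float = 0.5,
    max_evalue: float = 1e-3,
) -> bool:
    """The confident-match predicate: significant E plus identity and
    coverage floors (all bounds inclusive)."""
    return (
        match.evalue <= max_evalue
        and match.identity >= min_identity
        and match.query_cov >= min_query_cov
    )


@dataclass
class ContigClass:
    contig_id: str
    label: str  # annotated | conserved_uncharacterised | no_orf
    orf: OrfRecord | None = None
    best_hit: Alignment | None = None
    best_hit_db: str | None = None
    prior_assembly_support: bool | None = None
    evidence: list[str] = field(default_factory=list)


def classify_contig(
    contig_id: str,
    contig: str,
    ref_db: dict[str, str],
    comparator_dbs: dict[str, dict[str, str]],
    prior_assembly: dict[str, str] | None = None,
    min_aa: int = 33,
    max_candidates: int = 5,
    min_evalue: float = 1e-3,
    min_identity: float = 0.35,
    min_query_cov: float = 0.5,
    prefilter: bool = False,
) -> ContigClass:
    """Run the classification cascade for one contig.

    ORF candidates (the ``max_candidates`` longest across modes) are
    searched against the reference database first, then against every
    comparator database; the first confident hit fixes the class and the
    ORF.  Contigs with no confident hit anywhere are ``no_orf`` and, when
    a prior assembly is supplied, the strict cross-check result is
    recorded as supporting evidence.
    """
    candidates = find_orfs(contig, contig_id, min_aa=min_aa)
    candidates = sorted(candidates, key=lambda r: -r.aa_length)[:max_candidates]

    def scan(db: dict[str, str], db_name: str) -> tuple[OrfRecord, Alignment] | None:
        best: tuple[OrfRecord, Alignment] | None = None
        for cand in candidates:
            for hit in search(
                cand.aa, db, cand.fasta_id(), min_evalue, prefilter=prefilter
            ):
                if is_confident(hit, min_identity, min_query_cov, min_evalue):
                    if best is None or hit.evalue < best[1].evalue:
                        best = (cand, hit)
                    break  # hits are ranked; first confident is the best here
        return best

    found = scan(ref_db, "reference") if ref_db else None
    if found is not None:
        orf, hit = found
        return ContigClass(
            contig_id,
            "annotated",
            orf=orf,
            best_hit=hit,
            best_hit_db="reference",
            evidence=[f"confident reference hit {hit.subject_id} (E={hit.evalue:.2e})"],
        )
    for db_name, db in sorted(comparator_dbs.items()):
        found = scan(db, db_name)
        if found is not None:
            orf, hit = found
            return ContigClass(
                contig_id,
                "conserved_uncharacterised",
                orf=orf,
                best_hit=hit,
                best_hit_db=db_name,
                evidence=[
                    f"confident comparator hit {hit.subject_id} in {db_name} (E={hit.evalue:.2e})"
                ],
            )
    support = None
    if prior_assembly:
        support = noorf_crosscheck(contig, prior_assembly)
    return ContigClass(
        contig_id,
        "no_orf",
        prior_assembly_support=support,
        evidence=["no confident hit in reference or comparator databases"],
    )


def _crosscheck_one(contig: str, prior: str, min_identity: float, terminal_window: int) -> bool:
    res = edlib.align(contig, prior, mode="NW", task="path")
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"] or "")]
    n = len(contig)

    def in_terminal(p: int) -> bool:
        return p <= terminal_window or p >= n - terminal_window

    matches = columns = 0
    qpos = 0  # position in contig
    internal_gap = False
    for num, op in ops:
        if op == "=":
            matches += num
            columns += num
            qpos += num
        elif op in ("X", "M"):
            columns += num
            qpos += num
        else:  # indel: tolerated (and excluded from identity) at the ends only
            if not in_terminal(qpos):
                internal_gap = True
                columns += num
            if op == "I":  # bases present in contig only
                qpos += num
    if internal_gap:
        return False
    return columns > 0 and matches / columns >= min_identity


def noorf_crosscheck(
    contig: str,
    prior_assembly: dict[str, str],
    len_ratio_min: float = 0.9,
    min_identity: float = 0.98,
    terminal_window: int = 30,
) -> bool:
    """Strict match of a no-ORF contig against a prior assembly.

    True iff some prior contig has length ratio >= ``len_ratio_min``,
    aligned identity >= ``min_identity`` and no gap opening outside the
    terminal windows (either orientation).
    """
    if not prior_assembly:
        raise ValueError("prior assembly is empty")
    n = len(contig)
    for pid in sorted(prior_assembly):
        prior = prior_assembly[pid]
        ratio = min(n, len(prior)) / max(n, len(prior))
        if ratio < len_ratio_min:
            continue
        if _crosscheck_one(contig, prior, min_identity, terminal_window):
            return True
        if _crosscheck_one(contig, reverse_complement(prior), min_identity, terminal_window):
            return True
    return False
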