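"""Redundancy removal and assembly-refinement flagging.

Redundancy removal follows the greedy longest-first clustering convention
of identity-based dedup tools: identity is computed over the shorter
sequence (so contained fragments count as duplicates of their parent) and
both orientations are considered, since assemblers emit either strand.

Refinement detectors flag three assembly artefacts against a homologous
protein: fragment pairs that should be one transcript, retained introns
(a GT...AG-bounded insert splitting the homology into two collinear
blocks), and single-base indels that interrupt the reading frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
from Bio.Seq import reverse_complement

from .orfs import translate

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


# ---------------------------------------------------------------------------
# identity + clustering
# ---------------------------------------------------------------------------

def _match_fraction(query: str, target: str) -> float:
    """Matched positions / len(query), best infix placement of query in target."""
    res = edlib.align(query, target, mode="HW", task="path")
    matches = sum(
        int(n) for n, op in _CIGAR_RE.findall(res["cigar"] or "") if op == "="
    )
    return matches / len(query)


def pairwise_identity(a: str, b: str) -> float:
    """Identity between two nucleotide sequences in [0, 1].

    End-gap-free alignment of the shorter sequence within the longer;
    identity = matched positions / length of the shorter sequence, taking
    the best of the two orientations of ``b``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    fwd = _match_fraction(query, target)
    if fwd == 1.0:
        return 1.0
    rev = _match_fraction(query, reverse_complement(target))
    return max(fwd, rev)


@dataclass
class ClusterSet:
    """A partition of contigs with one representative per cluster."""

    clusters: dict[str, list[str]] = field(default_factory=dict)  # rep -> members

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    def member_to_rep(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items() for m in members}


def greedy_cluster(contigs: dict[str, str], identity_threshold: float = 0.95) -> ClusterSet:
    """Greedy longest-first identity clustering.

    Contigs are visited by decreasing length (ties by id); each joins the
    first existing representative it matches at >= ``identity_threshold``,
    otherwise it founds a new cluster.  Because visiting order is longest
    first, every representative is the longest member of its cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(contigs, key=lambda cid: (-len(contigs[cid]), cid))
    cs = ClusterSet()
    for cid in order:
        seq = contigs[cid]
        for rep in cs.clusters:
            if pairwise_identity(seq, contigs[rep]) >= identity_threshold:
                cs.clusters[rep].append(cid)
                break
        else:
            cs.clusters[cid] = [cid]
    return cs


def curate_isoforms(
    members: dict[str, str],
    identity_threshold: float = 0.95,
    terminal_window: int = 30,
) -> dict[str, str]:
    """Containment-based redundancy verdicts within an isoform group.

    A member is redundant when, ignoring its terminal ``terminal_window``
    bp, it is contained within a longer retained member at >= the identity
    threshold.  Returns id -> 'redundant' | 'retained'.
    """
    verdicts = {cid: "retained" for cid in members}
    order = sorted(members, key=lambda cid: (len(members[cid]), cid))
    for idx, cid in enumerate(order):
        seq = members[cid]
        core = seq[terminal_window:-terminal_window] if len(seq) > 2 * terminal_window else seq
        if not core:
            continue
        for other in order[idx + 1 :]:
            if verdicts[other] == "redundant":
                continue
            target = members[other]
            best = max(
                _match_fraction(core, target),
                _match_fraction(core, reverse_complement(target)),
            )
            if best >= identity_threshold:
                verdicts[cid] = "redundant"
                break
    return verdicts


# ---------------------------------------------------------------------------
# refinement flags
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefinementFlag:
    contig_id: str
    kind: str  # fragment_pair | intron_retention | frameshift | contaminant
    evidence: str
    corrected: str | None = None


def merge_fragments(
    a: str,
    b: str,
    min_overlap: int = 20,
    min_identity: float = 0.95,
) -> str | None:
    """Merge two fragments of one transcript over their sequence overlap.

    If a suffix of one fragment matches a prefix of the other over at
    least ``min_overlap`` bp at >= ``min_identity``, the concatenation
    with the overlap collapsed once is returned; otherwise None.  The
    longest qualifying overlap wins.
    """
    for x, y in ((a, b), (b, a)):
        limit = min(len(x), len(y))
        for ov in range(limit, min_overlap - 1, -1):
            suffix, prefix = x[-ov:], y[:ov]
            matches = sum(1 for p, q in zip(suffix, prefix) if p == q)
            if matches / ov >= min_identity:
                return x + y[ov:]
    return None


@dataclass(frozen=True)
class _Block:
    """A gap-free homology block between a contig frame and a protein."""

    strand: str
    frame: int
    nt_start: int  # forward-strand contig coords
    nt_end: int
    q_start: int  # protein coords
    q_end: int


def alignment_blocks(
    contig: str, protein: str, k: int = 4, min_block_aa: int = 8
) -> list[_Block]:
    """Gap-free diagonal match blocks between six-frame translations and a protein.

    Exact k-mer seeds are grouped per (strand, frame, diagonal) and merged
    into maximal runs; blocks shorter than ``min_block_aa`` residues are
    dropped.  Returned sorted by protein position then contig position.
    """
    kmers: dict[str, list[int]] = {}
    for i in range(len(protein) - k + 1):
        kmers.setdefault(protein[i : i + k], []).append(i)
    blocks: list[_Block] = []
    n = len(contig)
    for strand in ("+", "-"):
        for frame in (0, 1, 2):
            t = translate(contig, frame, strand)
            diag_hits: dict[int, list[int]] = {}
            for j in range(len(t) - k + 1):
                for i in kmers.get(t[j : j + k], ()):
                    diag_hits.setdefault(j - i, []).append(j)
            for diag, js in diag_hits.items():
                js.sort()
                run_start = prev = js[0]
                runs = []
                for j in js[1:]:
                    # merge through short seed droughts (isolated mismatches
                    # against a diverged homolog) — same diagonal, so no indel
                    if j - prev > 3 * k:
                        runs.append((run_start, prev + k))
                        run_start = j
                    prev = j
                runs.append((run_start, prev + k))
                for t0, t1 in runs:
                    if t1 - t0 < min_block_aa:
                        continue
                    nt0, nt1 = frame + 3 * t0, frame + 3 * t1
                    if strand == "-":
                        nt0, nt1 = n - nt1, n - nt0
                    blocks.append(_Block(strand, frame, nt0, nt1, t0 - diag, t1 - diag))
    blocks.sort(key=lambda b: (b.q_start, b.nt_start))
    return blocks


def _collinear_pairs(blocks: list[_Block], max_q_gap: int = 5):
    """Consecutive same-strand block pairs in consistent protein order."""
    for b1, b2 in zip(blocks, blocks[1:]):
        if b1.strand != b2.strand:
            continue
        q_gap = b2.q_start - b1.q_end
        if -2 <= q_gap <= max_q_gap:
            if b1.strand == "+" and b2.nt_start >= b1.nt_end - 6:
                yield b1, b2
            elif b1.strand == "-" and b1.nt_start >= b2.nt_end - 6:
                yield b2, b1  # left block on the contig first


def _excision_restores_protein(
    contig: str, gt: int, ag: int, protein: str, left: _Block, min_match: float = 0.8
) -> bool:
    """Does excising [gt, ag) re-translate to the protein across the junction?

    Guards boundary snapping: an excision is only believed when the
    corrected sequence locally encodes the homolog around the junction,
    so arbitrary GT/AG pairs inside an unexplained insert are rejected.
    """
    corrected = contig[:gt] + contig[ag:]
    t = translate(corrected[left.nt_start :], 0, "+")
    j = (gt - left.nt_start) // 3  # junction residue index in the translation
    window = range(max(0, j - 5), min(len(t), j + 5))
    if not window:
        return False
    hits = sum(
        1
        for i in window
        if left.q_start + i < len(protein) and t[i] == protein[left.q_start + i]
    )
    return hits >= min_match * len(list(window))


def detect_intron_retention(
    contig_id: str,
    contig: str,
    homolog_protein: str,
    min_intron: int = 50,
    snap_window: int = 12,
) -> RefinementFlag | None:
    """Flag a retained intron: a GT...AG insert splitting the homology.

    Requires two collinear homology blocks whose unaligned contig insert
    is >= ``min_intron`` nt, begins GT and ends AG.  Block edges from
    k-mer seeding can be off by a codon when the junction codon
    coincidentally re-encodes a flanking residue, so boundaries may be
    snapped within ``snap_window`` nt — but a snapped excision is accepted
    only if it demonstrably restores the homolog across the junction.
    The proposed correction excises the insert.
    """
    blocks = alignment_blocks(contig, homolog_protein)
    for left, right in _collinear_pairs(blocks):
        ins_start, ins_end = left.nt_end, right.nt_start
        if ins_end - ins_start < min_intron - snap_window:
            continue
        insert = contig[ins_start:ins_end]
        if (
            ins_end - ins_start >= min_intron
            and insert.startswith("GT")
            and insert.endswith("AG")
        ):
            return RefinementFlag(
                contig_id,
                "intron_retention",
                f"insert:{ins_start}-{ins_end}",
                corrected=contig[:ins_start] + contig[ins_end:],
            )
        if left.strand != "+":
            continue  # snapping verifies via forward-frame translation only
        gts = sorted(
            (
                p
                for p in range(max(0, ins_start - snap_window), ins_start + snap_window + 1)
                if contig[p : p + 2] == "GT"
            ),
            key=lambda p: abs(p - ins_start),
        )
        ags = sorted(
            (
                p
                for p in range(max(2, ins_end - snap_window), min(len(contig), ins_end + snap_window) + 1)
                if contig[p - 2 : p] == "AG"
            ),
            key=lambda p: abs(p - ins_end),
        )
        for gt in gts:
            for ag in ags:
                if ag - gt < min_intron:
                    continue
                if _excision_restores_protein(contig, gt, ag, homolog_protein, left):
                    return RefinementFlag(
                        contig_id,
                        "intron_retention",
                        f"insert:{gt}-{ag}",
                        corrected=contig[:gt] + contig[ag:],
                    )
    return None


def detect_frameshift(
    contig_id: str,
    contig: str,
    homolog_protein: str,
    max_junction: int = 10,
) -> RefinementFlag | None:
    """Flag a single-base indel interrupting the reading frame.

    Requires two collinear homology blocks in different frames whose
    contig junction is at most ``max_junction`` nt wide.
    """
    blocks = alignment_blocks(contig, homolog_protein)
    for left, right in _collinear_pairs(blocks):
        if left.frame == right.frame:
            continue
        junction = right.nt_start - left.nt_end
        if abs(junction) <= max_junction:
            return RefinementFlag(
                contig_id, "frameshift", f"junction:{left.nt_end}-{right.nt_start}"
            )
    return None
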