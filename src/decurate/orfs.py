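"""Six-frame open reading frame prediction.

Predicts ORFs on both strands of a contig in all three frames.  Besides
canonical ORFs (ATG through stop) three lower-stringency modes are
reported for truncated transcripts, which are common in de novo
assemblies: ``no_stop`` (ATG to contig end), ``no_start`` (frame start to
stop with no ATG in between) and ``internal`` (an uninterrupted reading
frame with neither boundary).  The default minimum length is 33 amino
acids, counted excluding the stop codon.

Coordinates are 0-based half-open on the forward strand throughout, so a
record's nucleotide span always slices the input contig directly.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: Mode preference used for sorting and best-ORF selection.
MODE_PRIORITY = {"canonical": 0, "no_stop": 1, "no_start": 2, "internal": 3}


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF anchored to forward-strand coordinates.

    ``start``/``end`` delimit the full span including the stop codon when
    the mode has one; ``aa`` excludes the stop.
    """

    contig_id: str
    strand: str  # "+" or "-"
    frame: int  # 0-2, offset on the strand the ORF was read from
    start: int  # forward-strand, 0-based inclusive
    end: int  # forward-strand, exclusive
    aa: str
    mode: str  # canonical | no_stop | no_start | internal

    @property
    def aa_length(self) -> int:
        return len(self.aa)

    @property
    def has_stop(self) -> bool:
        return self.mode in ("canonical", "no_start")

    def fasta_id(self) -> str:
        return (
            f"{self.contig_id}|{self.strand}|{self.frame}"
            f"|{self.start}-{self.end}|{self.mode}"
        )


def translate(nt: str, frame: int = 0, strand: str = "+") -> str:
    """Translate one frame of ``nt`` with the standard genetic code.

    Stops are rendered as ``*``; a trailing partial codon is dropped; any
    codon containing a character outside ACGT (e.g. N) becomes ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand == "-":
        nt = reverse_complement(nt)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = nt.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def _segment_orf(
    contig_id: str,
    aa_frame: str,
    seg_start: int,
    seg_end: int,
    has_stop: bool,
    frame: int,
    strand: str,
    seq_len: int,
) -> OrfRecord | None:
    """Build the single ORF record a stop-free codon segment yields.

    ``seg_start``/``seg_end`` are codon indices into the frame translation
    (stop codon excluded).  Which mode applies depends on whether the
    segment contains an ATG-encoded methionine and whether it is closed by
    a stop.
    """
    seg = aa_frame[seg_start:seg_end]
    m = seg.find("M")
    if m >= 0:
        first = seg_start + m
        mode = "canonical" if has_stop else "no_stop"
    else:
        first = seg_start
        mode = "no_start" if has_stop else "internal"
    aa = aa_frame[first:seg_end]
    if not aa:
        return None
    # codon coordinates on the read strand, stop codon included in the span
    nt_start = frame + 3 * first
    nt_end = frame + 3 * (seg_end + (1 if has_stop else 0))
    if strand == "-":
        nt_start, nt_end = seq_len - nt_end, seq_len - nt_start
    return OrfRecord(contig_id, strand, frame, nt_start, nt_end, aa, mode)


def find_orfs(
    contig: str,
    contig_id: str = "contig",
    min_aa: int = 33,
    allow_noncanonical: bool = True,
) -> list[OrfRecord]:
    """Predict ORFs in all six frames of ``contig``.

    Each maximal stop-free codon run contributes at most one record: from
    its first ATG when it has one (canonical / no_stop), otherwise from
    the run start (no_start / internal).  Records shorter than ``min_aa``
    residues are discarded.  The result is sorted by mode preference, then
    decreasing length, then position.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq_len = len(contig)
    records: list[OrfRecord] = []
    for strand in ("+", "-"):
        for frame in (0, 1, 2):
            aa_frame = translate(contig, frame, strand)
            seg_start = 0
            for pos, ch in enumerate(aa_frame):
                if ch == "*":
                    rec = _segment_orf(
                        contig_id, aa_frame, seg_start, pos, True, frame, strand, seq_len
                    )
                    if rec is not None:
                        records.append(rec)
                    seg_start = pos + 1
            rec = _segment_orf(
                contig_id, aa_frame, seg_start, len(aa_frame), False, frame, strand, seq_len
            )
            if rec is not None:
                records.append(rec)
    records = [r for r in records if r.aa_length >= min_aa]
    if not allow_noncanonical:
        records = [r for r in records if r.mode == "canonical"]
    records.sort(key=lambda r: (MODE_PRIORITY[r.mode], -r.aa_length, r.start, r.strand, r.frame))
    return records


def select_best_orf(
    orfs: list[OrfRecord], noncanonical_ratio: float = 1.5
) -> OrfRecord | None:
    """Pick a contig's single best ORF.

    The longest canonical ORF wins unless some non-canonical record is at
    least ``noncanonical_ratio`` times longer, in which case the longest
    non-canonical record is chosen.  Ties break by mode preference, then
    5'-most position.
    """
    if not orfs:
        return None

    def keyed(rs: list[OrfRecord]) -> OrfRecord:
        return min(rs, key=lambda r: (-r.aa_length, MODE_PRIORITY[r.mode], r.start, r.strand, r.frame))

    canonical = [r for r in orfs if r.mode == "canonical"]
    noncanon = [r for r in orfs if r.mode != "canonical"]
    if not canonical:
        return keyed(noncanon)
    best_c = keyed(canonical)
    if noncanon:
        best_n = keyed(noncanon)
        if best_n.aa_length >= noncanonical_ratio * best_c.aa_length:
            return best_n
    return best_c


def max_stopfree_run(contig: str) -> int:
    """Longest stop-free codon run (in codons) over all six frames.

    Used by the synthetic generator to certify that a contig cannot
    contain an ORF of a given length in any mode.
    """
    best = 0
    for strand in ("+", "-"):
        for frame in (0, 1, 2):
            for seg in translate(contig, frame, strand).split("*"):
                if len(seg) > best:
                    best = len(seg)
    return best
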