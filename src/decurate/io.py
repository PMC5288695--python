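"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices are tab-delimited with a header row of sample ids and a
first column of contig ids.  Sample sheets are CSV with columns
``sample_id``, ``timepoint_hps`` and ``replicate``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = str | Path


def read_fasta(path: PathLike) -> dict[str, str]:
    """Load a FASTA file into an id -> sequence mapping (insertion order kept)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_counts(path: PathLike) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.isna().any().any():
        raise ValueError(f"count matrix {path} contains missing values")
    return counts


def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="contig_id")


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = {"sample_id", "timepoint_hps", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: PathLike) -> None:
    sheet.to_csv(path, index=False)


def groups_by_timepoint(sheet: pd.DataFrame) -> dict[int, list[str]]:
    """Map each time point (hps) to its sample ids, in sheet order."""
    out: dict[int, list[str]] = {}
    for _, row in sheet.iterrows():
        out.setdefault(int(row["timepoint_hps"]), []).append(str(row["sample_id"]))
    return out
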