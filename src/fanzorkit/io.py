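"""Thin FASTA/FASTQ/TSV wrappers around Biopython SeqIO."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence; raises on duplicate identifiers."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> None:
    """Constant quality 'I' (Q40); qualities are not used downstream."""
    with open(path, "w") as fh:
        for k, read in enumerate(reads):
            fh.write(f"@{prefix}_{k}\n{read}\n+\n{'I' * len(read)}\n")
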