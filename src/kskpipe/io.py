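"""Plain-text sequence I/O with byte-deterministic writers.

Readers go through Biopython; writers are explicit so that repeated runs with
the same seed produce byte-identical FASTA/FASTQ, which the pipeline manifest
digests rely on.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(identifier, sequence)`` pairs as unwrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(
    records: Iterable[tuple[str, str]], path: str | os.PathLike, quality_char: str = "I"
) -> None:
    """Write reads with a constant Sanger quality (qualities are unused downstream)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def iter_reads(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Iterate ``(id, sequence)`` from FASTA or FASTQ, sniffing the format."""
    fmt = "fastq"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(">"):
            fmt = "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()
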