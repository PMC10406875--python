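"""Shared sequence I/O and small sequence utilities.

FASTA goes through Biopython's ``SeqIO``; FASTQ parsing uses the fast
``FastqGeneralIterator`` wrapped so that malformed records are reported with
their record index. All readers transparently handle gzip (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def phred_values(qual: str) -> list[int]:
    """Decode a Sanger/Illumina-1.8 quality string to Phred integers."""
    return [ord(c) - PHRED_OFFSET for c in qual]


def phred_string(values: Iterable[int]) -> str:
    return "".join(chr(v + PHRED_OFFSET) for v in values)


@dataclass(frozen=True)
class Read:
    """One sequencing read: name (no leading '@'), bases, quality string."""

    name: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.name!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


ReadPair = tuple[Read, Read]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield reads from a (possibly gzipped) FASTQ file.

    Raises ValueError naming the 1-based record index on truncated records or
    sequence/quality length mismatches.
    """
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {index + 1}: {exc}") from exc
            index += 1
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: malformed FASTQ record {index}: sequence/quality length mismatch"
                )
            yield Read(title.split()[0] if title else "", seq, qual)


def write_fastq(path: str | Path, reads: Iterable[Read]) -> int:
    """Write 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.name}\n{read.seq}\n+\n{read.qual}\n")
            n += 1
    return n


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Yield synchronized read pairs from _R1/_R2 FASTQ files."""
    it1, it2 = read_fastq(r1), read_fastq(r2)
    for mate1 in it1:
        try:
            mate2 = next(it2)
        except StopIteration:
            raise ValueError(f"{r2} has fewer records than {r1}") from None
        yield mate1, mate2
    if next(it2, None) is not None:
        raise ValueError(f"{r2} has more records than {r1}")


def write_fastq_pairs(r1: str | Path, r2: str | Path, pairs: Iterable[ReadPair]) -> int:
    n = 0
    with _open_text(r1, "wt") as h1, _open_text(r2, "wt") as h2:
        for mate1, mate2 in pairs:
            h1.write(f"@{mate1.name}\n{mate1.seq}\n+\n{mate1.qual}\n")
            h2.write(f"@{mate2.name}\n{mate2.seq}\n+\n{mate2.qual}\n")
            n += 1
    return n


def mates(pairs: Iterable[ReadPair]) -> Iterator[Read]:
    """Flatten read pairs into a stream of mates (R1 then R2 per pair)."""
    for mate1, mate2 in pairs:
        yield mate1
        yield mate2


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file as [(id, sequence), ...]."""
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> int:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with _open_text(path, "wt") as handle:
        return SeqIO.write(recs, handle, "fasta")
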