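"""Sex-specific k-mer screen: trim, count, filter, select MSKs, extract reads.

The screen contrasts a male and a female pooled read set. Only k-mers of a
fixed length (default 35) that start with a fixed dinucleotide prefix
(default "AG") are counted — a 1/16 subsample of k-mer space that preserves
sensitivity while cutting table size. K-mers whose total (male + female)
count falls outside [min_total_count, max_total_count] are discarded as
sequencing errors or repeats. The survivors with a female count of exactly
zero are the pure male-specific k-mers (MSKs); read pairs carrying at least
one MSK in either mate are the candidates handed to assembly.

K-mers are taken from reads exactly as sequenced, with no reverse-complement
canonicalization: the prefix filter is orientation-specific, and both strands
of any locus are sampled across a pool anyway.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable

from .io import Read, ReadPair, phred_values

#: k-mer -> (male_count, female_count)
KmerTable = dict[str, tuple[int, int]]
MskSet = set[str]


@dataclass(frozen=True)
class KmerScreenParams:
    k: int = 35
    required_prefix: str = "AG"
    min_total_count: int = 2
    max_total_count: int = 200
    #: count every occurrence within a read (True) or presence per read (False)
    count_multiplicity: bool = True

    def __post_init__(self) -> None:
        if self.k <= len(self.required_prefix):
            raise ValueError("k must exceed the prefix length")
        if not (0 < self.min_total_count <= self.max_total_count):
            raise ValueError("need 0 < min_total_count <= max_total_count")


@dataclass(frozen=True)
class TrimParams:
    """3' sliding-window quality trim settings (window mean below
    ``min_mean_quality`` trims; trailing bases below it are then removed)."""

    window: int = 4
    min_mean_quality: int = 20
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


def trimmed_length(quals: list[int], params: TrimParams) -> int:
    """Length kept after 3' sliding-window + trailing-base quality trimming."""
    n = len(quals)
    thr = params.min_mean_quality
    w = params.window
    while n >= w and sum(quals[n - w : n]) / w < thr:
        n -= 1
    while n > 0 and quals[n - 1] < thr:
        n -= 1
    return n


def quality_trim(pairs: Iterable[ReadPair], params: TrimParams) -> list[ReadPair]:
    """Trim low-quality 3' ends; drop a pair when either mate ends up shorter
    than ``min_length``. Trimming never touches 5' bases."""
    out: list[ReadPair] = []
    for index, (mate1, mate2) in enumerate(pairs):
        trimmed = []
        keep = True
        for mate in (mate1, mate2):
            if len(mate.seq) != len(mate.qual):
                raise ValueError(f"malformed record at pair index {index}: {mate.name!r}")
            n = trimmed_length(phred_values(mate.qual), params)
            if n < params.min_length:
                keep = False
                break
            trimmed.append(Read(mate.name, mate.seq[:n], mate.qual[:n]))
        if keep:
            out.append((trimmed[0], trimmed[1]))
    return out


def extract_prefixed_kmers(sequence: str, params: KmerScreenParams) -> list[str]:
    """All prefix-anchored k-mers of ``sequence`` in order of start position.

    K-mers containing N (or any non-ACGT base) are skipped.
    """
    k = params.k
    prefix = params.required_prefix
    out: list[str] = []
    limit = len(sequence) - k
    if prefix:
        pos = sequence.find(prefix)
        while 0 <= pos <= limit:
            kmer = sequence[pos : pos + k]
            if "N" not in kmer:
                out.append(kmer)
            pos = sequence.find(prefix, pos + 1)
    else:
        for pos in range(limit + 1):
            kmer = sequence[pos : pos + k]
            if "N" not in kmer:
                out.append(kmer)
    return out


def _count_reads(
    reads: Iterable[Read], params: KmerScreenParams, partition: str | None = None
) -> Counter:
    counts: Counter = Counter()
    plen = len(params.required_prefix)
    for read in reads:
        kmers = extract_prefixed_kmers(read.seq, params)
        if partition is not None:
            kmers = [km for km in kmers if km[plen : plen + len(partition)] == partition]
        if not params.count_multiplicity:
            kmers = set(kmers)
        counts.update(kmers)
    return counts


def count_pool_kmers(
    male_reads: Iterable[Read],
    female_reads: Iterable[Read],
    params: KmerScreenParams,
    partitions: int = 1,
) -> KmerTable:
    """Per-pool occurrence counts for every prefix-anchored k-mer (unfiltered).

    With ``partitions`` > 1 the inputs are traversed once per partition (keyed
    on the bases following the prefix), bounding peak memory to roughly
    1/partitions of the table — the inputs must then be re-iterable (lists,
    not generators). Supported partition counts: 1, 4, 16.
    """
    if partitions == 1:
        keys: list[str | None] = [None]
    elif partitions in (4, 16):
        depth = 1 if partitions == 4 else 2
        keys = ["".join(p) for p in product("ACGT", repeat=depth)]
    else:
        raise ValueError("partitions must be 1, 4 or 16")

    table: KmerTable = {}
    for key in keys:
        male = _count_reads(male_reads, params, key)
        female = _count_reads(female_reads, params, key)
        for kmer in male.keys() | female.keys():
            table[kmer] = (male.get(kmer, 0), female.get(kmer, 0))
    return table


def filter_and_select_msks(
    table: KmerTable, params: KmerScreenParams
) -> tuple[KmerTable, MskSet]:
    """Apply the total-count band and pick the pure male-specific k-mers.

    A k-mer survives iff min_total_count <= male + female <= max_total_count;
    a survivor is an MSK iff its female count is zero.
    """
    filtered: KmerTable = {}
    msks: MskSet = set()
    lo, hi = params.min_total_count, params.max_total_count
    for kmer, (m, f) in table.items():
        total = m + f
        if lo <= total <= hi:
            filtered[kmer] = (m, f)
            if f == 0:
                msks.add(kmer)
    return filtered, msks


def extract_candidate_read_pairs(
    pairs: Iterable[ReadPair], msks: MskSet, params: KmerScreenParams
) -> list[ReadPair]:
    """Keep pairs in which at least one mate contains at least one MSK.

    Because every MSK is a prefix-anchored k-mer, substring containment is
    equivalent to membership of one of the mate's own prefix-anchored k-mers
    in the MSK set.
    """
    out: list[ReadPair] = []
    for mate1, mate2 in pairs:
        if any(
            km in msks
            for mate in (mate1, mate2)
            for km in extract_prefixed_kmers(mate.seq, params)
        ):
            out.append((mate1, mate2))
    return out


def run_screen(
    male_pairs: list[ReadPair],
    female_pairs: list[ReadPair],
    params: KmerScreenParams,
    trim: TrimParams | None = None,
) -> tuple[KmerTable, MskSet, list[ReadPair]]:
    """Trim both pools, build the filtered k-mer table, and extract the
    MSK-bearing male read pairs. Convenience wrapper over the stage functions."""
    if trim is not None:
        if trim.min_length < params.k:
            warnings.warn(
                "trim min_length below k: trimmed reads may yield no k-mers",
                stacklevel=2,
            )
        male_pairs = quality_trim(male_pairs, trim)
        female_pairs = quality_trim(female_pairs, trim)
    from .io import mates

    table = count_pool_kmers(list(mates(male_pairs)), list(mates(female_pairs)), params)
    filtered, msks = filter_and_select_msks(table, params)
    candidates = extract_candidate_read_pairs(male_pairs, msks, params)
    return filtered, msks, candidates
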