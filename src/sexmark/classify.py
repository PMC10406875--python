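"""Zero-mismatch map-back of both pools onto scaffolds and depth classification.

A read maps wherever it (or its reverse complement) is an exact substring of
a scaffold; no mismatches are tolerated and multi-mapping reads count toward
every scaffold they hit — conservative for the female-zero rule, since any
female evidence disqualifies a scaffold. A scaffold with male reads and zero
female reads is MALE_SPECIFIC; one whose male mean depth is at least
``rescue_ratio`` (default 2) times its nonzero female mean depth is
RESCUED_MALE_SPECIFIC (hemizygous loci with a diverged female paralog show
exactly this halved-female-depth signature); everything else is PENDING.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .assembly import Scaffold
from .io import Read, revcomp


class Label(str, Enum):
    MALE_SPECIFIC = "MALE_SPECIFIC"
    RESCUED_MALE_SPECIFIC = "RESCUED_MALE_SPECIFIC"
    PENDING = "PENDING"


@dataclass(frozen=True)
class ExactHit:
    scaffold_id: str
    start: int
    strand: str  # "+" read matches forward, "-" reverse complement matches


@dataclass
class CoverageProfile:
    scaffold_id: str
    scaffold_length: int
    male_mapped_reads: int = 0
    female_mapped_reads: int = 0
    male_mapped_bases: int = 0
    female_mapped_bases: int = 0

    @property
    def male_mean_depth(self) -> float:
        return self.male_mapped_bases / self.scaffold_length

    @property
    def female_mean_depth(self) -> float:
        return self.female_mapped_bases / self.scaffold_length


@dataclass
class ScaffoldReport:
    scaffold: Scaffold
    profile: CoverageProfile
    label: Label


def _find_all(text: str, pattern: str) -> list[int]:
    """All (overlapping) occurrence starts of pattern in text."""
    hits = []
    pos = text.find(pattern)
    while pos != -1:
        hits.append(pos)
        pos = text.find(pattern, pos + 1)
    return hits


def map_exact(read: str | Read, scaffolds: Iterable[Scaffold]) -> list[ExactHit]:
    """Every exact placement of the read on either strand of any scaffold.

    Reference semantics by direct substring scan; ScaffoldIndex gives the same
    answers with seed-and-verify lookup.
    """
    seq = read.seq if isinstance(read, Read) else read
    rc = revcomp(seq)
    hits = []
    for scaffold in scaffolds:
        for pos in _find_all(scaffold.sequence, seq):
            hits.append(ExactHit(scaffold.id, pos, "+"))
        for pos in _find_all(scaffold.sequence, rc):
            hits.append(ExactHit(scaffold.id, pos, "-"))
    return hits


class ScaffoldIndex:
    """Seed-and-verify exact matcher over a scaffold set.

    Indexes every ``seed_length``-mer position of every scaffold; a query's
    first seed (forward and reverse complement) nominates candidate
    placements, each verified by full string comparison. Identical in output
    to the full substring scan for queries of length >= seed_length; shorter
    queries fall back to scanning.
    """

    def __init__(self, scaffolds: Iterable[Scaffold], seed_length: int = 20):
        self.scaffolds = list(scaffolds)
        self.seed_length = seed_length
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for si, scaffold in enumerate(self.scaffolds):
            seq = scaffold.sequence
            for pos in range(len(seq) - seed_length + 1):
                self._seeds.setdefault(seq[pos : pos + seed_length], []).append((si, pos))

    def map(self, read: str | Read) -> list[ExactHit]:
        seq = read.seq if isinstance(read, Read) else read
        if len(seq) < self.seed_length:
            return map_exact(seq, self.scaffolds)
        hits = []
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            seen: set[tuple[int, int]] = set()
            for si, pos in self._seeds.get(query[: self.seed_length], ()):
                scaffold = self.scaffolds[si]
                if (si, pos) in seen:
                    continue
                seen.add((si, pos))
                if scaffold.sequence[pos : pos + len(query)] == query:
                    hits.append(ExactHit(scaffold.id, pos, strand))
        hits.sort(key=lambda h: (h.scaffold_id, h.start, h.strand))
        return hits


def profile_coverage(
    male_reads: Iterable[Read],
    female_reads: Iterable[Read],
    scaffolds: list[Scaffold],
    seed_length: int = 20,
) -> list[CoverageProfile]:
    """Mapped-read counts and mean per-base depths per scaffold and pool.

    A read contributes once to every scaffold it hits (regardless of how many
    placements it has within that scaffold); mean depth is total mapped read
    bases divided by scaffold length.
    """
    if not scaffolds:
        raise ValueError("scaffold set is empty")
    index = ScaffoldIndex(scaffolds, seed_length)
    profiles = {
        s.id: CoverageProfile(s.id, s.length) for s in scaffolds
    }
    for pool, reads in (("male", male_reads), ("female", female_reads)):
        for read in reads:
            hit_ids = {h.scaffold_id for h in index.map(read)}
            for sid in hit_ids:
                prof = profiles[sid]
                if pool == "male":
                    prof.male_mapped_reads += 1
                    prof.male_mapped_bases += len(read.seq)
                else:
                    prof.female_mapped_reads += 1
                    prof.female_mapped_bases += len(read.seq)
    return [profiles[s.id] for s in scaffolds]


def classify_scaffolds(
    scaffolds: list[Scaffold],
    profiles: list[CoverageProfile],
    rescue_ratio: float = 2.0,
) -> list[ScaffoldReport]:
    """Label every scaffold exactly once.

    MALE_SPECIFIC: no female reads, at least one male read. RESCUED: nonzero
    female depth but male mean depth >= rescue_ratio x female mean depth
    (inclusive). PENDING otherwise.
    """
    by_id = {p.scaffold_id: p for p in profiles}
    reports = []
    for scaffold in scaffolds:
        prof = by_id[scaffold.id]
        if prof.female_mapped_reads == 0 and prof.male_mapped_reads > 0:
            label = Label.MALE_SPECIFIC
        elif (
            prof.female_mean_depth > 0
            and prof.male_mean_depth >= rescue_ratio * prof.female_mean_depth
        ):
            label = Label.RESCUED_MALE_SPECIFIC
        else:
            label = Label.PENDING
        reports.append(ScaffoldReport(scaffold, prof, label))
    return reports


def filter_candidates(reports: list[ScaffoldReport], min_length: int = 100) -> list[Scaffold]:
    """Male-specific and rescued scaffolds of at least ``min_length`` bases,
    longest first. Stands in for downstream gene-level prioritization."""
    kept = [
        r.scaffold
        for r in reports
        if r.label in (Label.MALE_SPECIFIC, Label.RESCUED_MALE_SPECIFIC)
        and r.scaffold.length >= min_length
    ]
    kept.sort(key=lambda s: (-s.length, s.id))
    return kept


def report_table(reports: list[ScaffoldReport]) -> pd.DataFrame:
    """Scaffold report as a tidy frame (the ``scaffold_report.tsv`` schema)."""
    rows = [
        {
            "scaffold_id": r.scaffold.id,
            "length": r.scaffold.length,
            "male_reads": r.profile.male_mapped_reads,
            "female_reads": r.profile.female_mapped_reads,
            "male_depth": round(r.profile.male_mean_depth, 4),
            "female_depth": round(r.profile.female_mean_depth, 4),
            "label": r.label.value,
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold_id",
            "length",
            "male_reads",
            "female_reads",
            "male_depth",
            "female_depth",
            "label",
        ],
    )
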