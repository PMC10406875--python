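"""Minimal de Bruijn unitig assembler for candidate male-biased read pairs.

Nodes are canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement; k is odd so no k-mer is its own reverse complement) with
occurrence counts; edges are the observed (k+1)-mers. Unitigs are maximal
non-branching paths, reported in canonical orientation. The only graph
cleaning is dead-end tip clipping (short, count-1 chains hanging off a
branch); there is no bubble popping, scaffolding or repeat resolution —
candidate regions are small and determinism matters more than contiguity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .io import Read, revcomp


@dataclass(frozen=True)
class AssemblyParams:
    graph_k: int = 31
    min_kmer_count: int = 2
    min_unitig_length: int = 100
    clip_tips: bool = True

    def __post_init__(self) -> None:
        if self.graph_k % 2 == 0:
            raise ValueError("graph_k must be odd")
        if self.graph_k < 15:
            raise ValueError("graph_k must be >= 15")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


@dataclass(frozen=True)
class Scaffold:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DeBruijnGraph:
    k: int
    nodes: dict[str, int]  # canonical k-mer -> count
    edges: set[str] = field(default_factory=set)  # canonical (k+1)-mers


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _clean_runs(seq: str) -> list[str]:
    """Split a sequence into maximal runs of A/C/G/T (drops N and friends)."""
    runs, cur = [], []
    for base in seq:
        if base in "ACGT":
            cur.append(base)
        elif cur:
            runs.append("".join(cur))
            cur = []
    if cur:
        runs.append("".join(cur))
    return runs


def build_graph(reads: Iterable[Read], params: AssemblyParams) -> DeBruijnGraph:
    """Count canonical k-mers and record observed (k+1)-mer edges.

    Nodes seen fewer than ``min_kmer_count`` times are dropped; edges touching
    dropped nodes are ignored at traversal time.
    """
    k = params.graph_k
    counts: Counter = Counter()
    edges: set[str] = set()
    any_long_enough = False
    for read in reads:
        for run in _clean_runs(read.seq.upper()):
            if len(run) < k:
                continue
            any_long_enough = True
            for i in range(len(run) - k + 1):
                counts[canonical(run[i : i + k])] += 1
            for i in range(len(run) - k):
                edges.add(canonical(run[i : i + k + 1]))
    if not any_long_enough:
        raise ValueError(f"graph_k={k} is not shorter than any input read")
    nodes = {km: c for km, c in counts.items() if c >= params.min_kmer_count}
    return DeBruijnGraph(k, nodes, edges)


def _successors(graph: DeBruijnGraph, oriented: str) -> list[str]:
    out = []
    for base in "ACGT":
        edge = oriented + base
        if canonical(edge) in graph.edges:
            nxt = edge[1:]
            if canonical(nxt) in graph.nodes:
                out.append(nxt)
    return out


def _predecessors(graph: DeBruijnGraph, oriented: str) -> list[str]:
    out = []
    for base in "ACGT":
        edge = base + oriented
        if canonical(edge) in graph.edges:
            prv = edge[:-1]
            if canonical(prv) in graph.nodes:
                out.append(prv)
    return out


def _walk_unitigs(graph: DeBruijnGraph) -> list[list[str]]:
    """Partition the node set into maximal non-branching oriented paths."""
    visited: set[str] = set()
    paths: list[list[str]] = []
    for start in sorted(graph.nodes):
        if start in visited:
            continue
        visited.add(start)
        path = [start]
        # extend 3'
        cur = start
        while True:
            nxt = _successors(graph, cur)
            if len(nxt) != 1 or len(_predecessors(graph, nxt[0])) != 1:
                break
            if canonical(nxt[0]) in visited:
                break
            cur = nxt[0]
            visited.add(canonical(cur))
            path.append(cur)
        # extend 5'
        cur = start
        while True:
            prv = _predecessors(graph, cur)
            if len(prv) != 1 or len(_successors(graph, prv[0])) != 1:
                break
            if canonical(prv[0]) in visited:
                break
            cur = prv[0]
            visited.add(canonical(cur))
            path.insert(0, cur)
        paths.append(path)
    return paths


def _path_sequence(path: list[str]) -> str:
    return path[0] + "".join(node[-1] for node in path[1:])


def _is_tip(graph: DeBruijnGraph, path: list[str], params: AssemblyParams) -> bool:
    """Dead-end chain, all counts 1, shorter than 2k, attached at one end only."""
    seq_len = len(path) + graph.k - 1
    if seq_len >= 2 * params.graph_k:
        return False
    if any(graph.nodes[canonical(n)] > 1 for n in path):
        return False
    head_free = not _predecessors(graph, path[0])
    tail_free = not _successors(graph, path[-1])
    return head_free != tail_free  # dangling off something, not isolated


def extract_unitigs(graph: DeBruijnGraph, params: AssemblyParams) -> list[Scaffold]:
    """Maximal non-branching paths as scaffolds, canonical orientation.

    Output order is deterministic: descending length, then lexicographic
    sequence; ids are ``scaffold_<n>`` in that order. Unitigs shorter than
    ``min_unitig_length`` are dropped after tip clipping.
    """
    paths = _walk_unitigs(graph)
    if params.clip_tips:
        tips = [p for p in paths if _is_tip(graph, p, params)]
        if tips:
            pruned = dict(graph.nodes)
            for path in tips:
                for node in path:
                    pruned.pop(canonical(node), None)
            graph = DeBruijnGraph(graph.k, pruned, graph.edges)
            paths = _walk_unitigs(graph)
    seqs = []
    for path in paths:
        seq = _path_sequence(path)
        seqs.append(min(seq, revcomp(seq)))
    seqs = [s for s in seqs if len(s) >= params.min_unitig_length]
    seqs.sort(key=lambda s: (-len(s), s))
    return [Scaffold(f"scaffold_{i + 1}", s) for i, s in enumerate(seqs)]


def assemble(reads: Iterable[Read], params: AssemblyParams) -> list[Scaffold]:
    """build_graph + extract_unitigs in one call."""
    return extract_unitigs(build_graph(reads, params), params)


def assembly_stats(scaffolds: list[Scaffold]) -> dict[str, int]:
    """n, total bp, and N50 of a scaffold set."""
    lengths = sorted((s.length for s in scaffolds), reverse=True)
    total = sum(lengths)
    n50 = 0
    running = 0
    for length in lengths:
        running += length
        if running * 2 >= total:
            n50 = length
            break
    return {"n_scaffolds": len(lengths), "total_bp": total, "n50": n50}
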