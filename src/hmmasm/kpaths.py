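"""Modified Yen's K-shortest-path enumeration for microheterogeneity.

Rank 1 is the plain A* best path.  Further candidates spur off previously
found paths (with Lawler's restriction: only at or after the point a path
branched from its own parent), banning each previously used continuation
edge, so every candidate differs from the known paths by at least one edge.
Two filters keep the ranked list informative rather than combinatorial:

* a candidate with no edge absent from all accepted paths is skipped
  without consuming a rank, and
* a completed candidate whose nucleotide kmers add nothing new over the
  accepted contigs is likewise skipped,

so each returned path carries new sequence information.  Rejected
candidates still serve as spur parents, which keeps the ranked output equal
to brute-force enumeration plus greedy filtering on small graphs.  Spur
searches reuse the pruning rule but never the best-path cache.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

from .cag_search import (
    SearchError,
    SearchResult,
    SearchStep,
    Vertex,
    astar_search,
)
from .kmer_graph import KmerCounter, canonical
from .profile_hmm import ProfileHMM, heuristic_table


@dataclass
class RankedPath:
    rank: int
    result: SearchResult
    nt: str
    modified_score: float
    raw_score: float


def path_nt(steps: list[SearchStep], direction: str) -> str:
    """Nucleotide sequence spelled by a directional path, start kmer included,
    in forward (left-to-right) orientation."""
    codons = [s.codon for s in steps[1:] if s.codon]
    k0 = steps[0].vertex.kmer
    if direction == "right":
        return k0 + "".join(codons)
    return "".join(reversed(codons)) + k0


def _nt_kmers(nt: str, k: int) -> set[str]:
    return {canonical(nt[i : i + k]) for i in range(len(nt) - k + 1)}


def _edges(steps: list[SearchStep]) -> set[tuple[Vertex, Vertex]]:
    return {(steps[i].vertex, steps[i + 1].vertex) for i in range(len(steps) - 1)}


def k_shortest_paths(
    start: Vertex,
    model: ProfileHMM,
    counter: KmerCounter,
    K: int,
    *,
    min_count: int = 1,
    prune: Optional[int] = 20,
    direction: str = "right",
    kmer_k: Optional[int] = None,
    max_spur_attempts: Optional[int] = None,
    heuristic: Optional[dict] = None,
) -> list[RankedPath]:
    """Up to ``K`` ranked start-to-goal paths with non-increasing scores.

    Returns fewer than ``K`` paths when candidates are exhausted (a normal
    outcome).  ``kmer_k`` is the nucleotide kmer length for the new-kmer
    filter (defaults to the counter's k).  ``max_spur_attempts`` bounds
    worst-case exploration (default ``100 * K``).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    kmer_k = kmer_k if kmer_k is not None else counter.k
    max_spur = max_spur_attempts if max_spur_attempts is not None else 100 * K
    h = heuristic if heuristic is not None else heuristic_table(model)

    best = astar_search(
        start, model, counter,
        min_count=min_count, prune=prune, cache=None,
        direction=direction, heuristic=h,
    )
    ranked = [RankedPath(1, best, path_nt(best.steps, direction),
                         best.modified_score, best.raw_score)]
    if K == 1 or best.partial or len(best.steps) < 2:
        return ranked

    accepted_edges = _edges(best.steps)
    accepted_kmers = _nt_kmers(ranked[0].nt, kmer_k)
    all_paths: list[tuple[list[SearchStep], int]] = [(best.steps, 0)]
    pending: list[tuple[list[SearchStep], int]] = [(best.steps, 0)]
    cand_heap: list = []
    seen: set[tuple[Vertex, ...]] = {best.vertices()}
    attempts = 0

    while True:
        while pending and attempts < max_spur:
            src_steps, branch_idx = pending.pop(0)
            for i in range(branch_idx, len(src_steps) - 1):
                if attempts >= max_spur:
                    break
                attempts += 1
                spur_v = src_steps[i].vertex
                root = src_steps[: i + 1]
                root_verts = tuple(s.vertex for s in root)
                banned = {
                    (other[i].vertex, other[i + 1].vertex)
                    for other, _ in all_paths
                    if len(other) > i + 1
                    and tuple(s.vertex for s in other[: i + 1]) == root_verts
                }
                root_interior = {s.vertex for s in root[:-1]}
                try:
                    spur = astar_search(
                        spur_v, model, counter,
                        min_count=min_count, prune=prune, cache=None,
                        direction=direction, heuristic=h,
                        banned_edges=banned, banned_vertices=root_interior,
                    )
                except SearchError:
                    continue
                if spur.partial:
                    continue
                total = list(root) + list(spur.steps[1:])
                verts = tuple(s.vertex for s in total)
                if verts in seen:
                    continue
                seen.add(verts)
                mod = sum(s.w_mod for s in total)
                raw = sum(s.w_raw for s in total)
                nt = path_nt(total, direction)
                heapq.heappush(cand_heap, (-mod, nt, verts, raw, i, total))
        if not cand_heap:
            break
        neg_mod, nt, verts, raw, branch_idx, steps = heapq.heappop(cand_heap)
        all_paths.append((steps, branch_idx))
        pending.append((steps, branch_idx))
        edges = _edges(steps)
        kmers = _nt_kmers(nt, kmer_k)
        if edges - accepted_edges and kmers - accepted_kmers:
            result = SearchResult(steps, -neg_mod, raw, False, 0)
            ranked.append(
                RankedPath(len(ranked) + 1, result, nt, -neg_mod, raw)
            )
            accepted_edges |= edges
            accepted_kmers |= kmers
            if len(ranked) >= K:
                break
    return ranked
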