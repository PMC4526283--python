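"""A* best-path search over the combined weighted assembly graph (CAG).

A CAG vertex pairs a de Bruijn kmer with a profile HMM state; only visited
vertices are ever materialised.  Match and insert moves take a codon step in
the nucleotide graph and emit the translated amino acid; delete moves keep
the kmer from the last match/insert (that carried kmer is what lets the
walk resume correctly after a deletion).  Search maximises the monotone
"modified" path score; the raw (unmodified) score rides along for the prune
rule, for choosing the best intermediate vertex when a search exhausts, and
for the final HMM bit score.

A full gene is assembled by two independent searches from one starting
kmer: rightwards under the forward model and leftwards under the reversed
model, mirrored at column ``L - j + 1``; the two paths and the seed are then
fused and rescored under the forward model.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .kmer_graph import KmerCounter, codon_neighbors, translate, translate_codon
from .profile_hmm import (
    AA_INDEX,
    ProfileHMM,
    bit_score,
    edge_weight,
    heuristic_table,
)
from .start_finder import StartingKmer


class Vertex(NamedTuple):
    """(kmer, model column, state type) — identity is the full triple."""

    kmer: str
    column: int
    state: str  # M, I, D


@dataclass(frozen=True)
class SearchStep:
    vertex: Vertex
    codon: Optional[str]  # None for the start vertex and delete steps
    w_mod: float
    w_raw: float


@dataclass
class SearchResult:
    steps: list[SearchStep]  # steps[0] is the start vertex with zero weights
    modified_score: float
    raw_score: float
    partial: bool
    opened: int

    def vertices(self) -> tuple[Vertex, ...]:
        return tuple(s.vertex for s in self.steps)


class SearchError(RuntimeError):
    """The search cannot start (e.g. seed kmer absent from the graph)."""


class RescoreError(ValueError):
    """A contig cannot be rescored (internal stop codon)."""


def successors(
    vertex: Vertex,
    model: ProfileHMM,
    counter: KmerCounter,
    min_count: int = 1,
    direction: str = "right",
) -> list[tuple[Vertex, Optional[str], float, float]]:
    """Expand one CAG vertex: (next vertex, emitted codon, modified, raw).

    Match/insert successors pair each legal profile transition with each
    codon-step neighbor in the graph; delete successors advance the column
    without a kmer step.  Stop-codon emissions are excluded, so paths never
    read through stops.  Dead ends simply return an empty list.
    """
    kmer, j, state = vertex
    L = model.L
    if j >= L:
        return []
    out: list[tuple[Vertex, Optional[str], float, float]] = []
    lt = model.log_trans
    c_next = float(model.max_emission_log[j + 1])
    neigh: Optional[list[tuple[str, str]]] = None

    match_t = {"M": "MM", "I": "IM", "D": "DM"}[state]
    tlog = float(lt[match_t][j])
    if tlog > -math.inf:
        neigh = codon_neighbors(counter, kmer, direction, min_count)
        for nk, codon in neigh:
            aa = translate_codon(codon)
            e = model.emission_logodds(j + 1, aa)
            if e == -math.inf:
                continue
            raw = tlog + e
            out.append((Vertex(nk, j + 1, "M"), codon, raw - c_next, raw))

    if state in ("M", "I"):
        tlog = float(lt["MI" if state == "M" else "II"][j])
        if tlog > -math.inf:
            if neigh is None:
                neigh = codon_neighbors(counter, kmer, direction, min_count)
            for nk, codon in neigh:
                if translate_codon(codon) not in AA_INDEX:
                    continue
                out.append((Vertex(nk, j, "I"), codon, tlog, tlog))

    if state in ("M", "D"):
        tlog = float(lt["MD" if state == "M" else "DD"][j])
        if tlog > -math.inf:
            out.append((Vertex(kmer, j + 1, "D"), None, tlog - c_next, tlog))
    return out


class _Node:
    __slots__ = ("vertex", "parent", "codon", "w_mod", "w_raw", "g", "raw",
                 "best_raw", "since_best")

    def __init__(self, vertex, parent, codon, w_mod, w_raw, g, raw, best_raw, since_best):
        self.vertex = vertex
        self.parent = parent
        self.codon = codon
        self.w_mod = w_mod
        self.w_raw = w_raw
        self.g = g
        self.raw = raw
        self.best_raw = best_raw
        self.since_best = since_best


_EPS = 1e-12


def _reconstruct(node: _Node) -> list[SearchStep]:
    steps = []
    while node is not None:
        steps.append(SearchStep(node.vertex, node.codon, node.w_mod, node.w_raw))
        node = node.parent
    steps.reverse()
    return steps


def trivial_result(vertex: Vertex) -> SearchResult:
    return SearchResult([SearchStep(vertex, None, 0.0, 0.0)], 0.0, 0.0, False, 0)


def astar_search(
    start: Vertex,
    model: ProfileHMM,
    counter: KmerCounter,
    *,
    min_count: int = 1,
    prune: Optional[int] = 20,
    cache: Optional[dict] = None,
    direction: str = "right",
    heuristic: Optional[dict] = None,
    banned_edges: Optional[set] = None,
    banned_vertices: Optional[set] = None,
) -> SearchResult:
    """Best-first search from ``start`` to any terminal-column M or D vertex.

    The open set is ordered by ``f = g + h`` with deterministic tie-breaking
    (higher raw score, then insertion order).  A popped vertex whose raw
    score has not improved within ``prune`` openings is discarded
    (``prune=None`` or a negative value disables the rule).  Vertices on a
    cached best path open only the next cached vertex.  If the open set
    exhausts before the model end, the path to the best intermediate raw
    scorer is returned and flagged partial.  Vertices may be re-expanded
    when a strictly better prefix score is found, so the first goal popped
    is optimal whenever the heuristic is admissible.
    """
    if counter.count(start.kmer) < min_count:
        raise SearchError(f"starting kmer {start.kmer!r} absent from the graph")
    h = heuristic if heuristic is not None else heuristic_table(model)
    L = model.L

    def hval(v: Vertex) -> float:
        return float(h[v.state][v.column])

    prune_on = prune is not None and prune >= 0
    seq = itertools.count()
    root = _Node(start, None, None, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    heap: list = [(-hval(start), 0.0, next(seq), root)]
    best_g: dict[Vertex, float] = {start: 0.0}
    best_node = root
    opened = 0

    while heap:
        _, _, _, node = heapq.heappop(heap)
        v = node.vertex
        if node.g < best_g.get(v, -math.inf) - _EPS:
            continue  # superseded by a better path to the same vertex
        if v.column == L and v.state in ("M", "D"):
            steps = _reconstruct(node)
            if cache is not None:
                for a, b in zip(steps, steps[1:]):
                    cache.setdefault(a.vertex, (b.vertex, b.codon, b.w_mod, b.w_raw))
            return SearchResult(steps, node.g, node.raw, False, opened)
        if node.raw > best_node.raw + _EPS:
            best_node = node
        if prune_on and node.since_best > prune:
            continue
        opened += 1
        if cache is not None and v in cache:
            succs = [cache[v]]
        else:
            succs = successors(v, model, counter, min_count, direction)
        for nv, codon, w_mod, w_raw in succs:
            if banned_vertices and nv in banned_vertices:
                continue
            if banned_edges and (v, nv) in banned_edges:
                continue
            ng = node.g + w_mod
            if ng <= best_g.get(nv, -math.inf) + _EPS:
                continue
            best_g[nv] = ng
            nraw = node.raw + w_raw
            if nraw > node.best_raw + _EPS:
                nbest, nsince = nraw, 0
            else:
                nbest, nsince = node.best_raw, node.since_best + 1
            child = _Node(nv, node, codon, w_mod, w_raw, ng, nraw, nbest, nsince)
            heapq.heappush(heap, (-(ng + hval(nv)), -nraw, next(seq), child))

    steps = _reconstruct(best_node)
    return SearchResult(steps, best_node.g, best_node.raw, True, opened)


# ---------------------------------------------------------------------------
# Contigs and bidirectional assembly

@dataclass
class Contig:
    id: str
    gene: str
    nt: str
    aa: str
    bits: float
    raw_nats: float
    model_span: tuple[int, int]
    col_aa: dict[int, str] = field(repr=False)
    state_path: list = field(repr=False)
    partial: bool = False
    seed_id: str = ""
    rank: int = 1


def mirror_left_steps(steps: list[SearchStep], L: int) -> list[tuple[str, int, Optional[str]]]:
    """Map a reversed-model left path into forward (state, column, aa) order.

    The shared start vertex is dropped.  Reverse column ``r`` mirrors to
    forward column ``L - r + 1`` for match/delete states; a reverse insert
    between columns ``r`` and ``r+1`` becomes the forward insert ``I_{L-r}``.
    Reversing the visit order then yields a legal forward-model path.
    """
    out: list[tuple[str, int, Optional[str]]] = []
    for st in steps[1:]:
        s = st.vertex.state
        r = st.vertex.column
        aa = translate_codon(st.codon) if st.codon else None
        if s == "I":
            out.append(("I", L - r, aa))
        else:
            out.append((s, L - r + 1, aa))
    out.reverse()
    return out


def rescore_state_path(path: list[tuple[str, int, Optional[str]]], model: ProfileHMM) -> float:
    """Deterministic raw-weight sum (nats) over an explicit state path.

    The first state contributes its emission only (no entering transition);
    this is what makes the score a function of the assembled sequence and
    its alignment, independent of which seed produced it.
    """
    total = 0.0
    prev: Optional[tuple[str, int]] = None
    for s, j, aa in path:
        if aa == "*":
            raise RescoreError(f"internal stop codon at column {j}")
        if prev is None:
            if s == "M":
                total += model.emission_logodds(j, aa)
        else:
            total += edge_weight(model, prev, (s, j), aa, variant="raw")
        prev = (s, j)
    return total


def rescore_contig(contig: Contig, model: ProfileHMM) -> float:
    """Standard HMM score (bits) of a contig from the unmodified weights."""
    return bit_score(rescore_state_path(contig.state_path, model))


def combine_results(
    starting: StartingKmer,
    left: SearchResult,
    right: SearchResult,
    fwd_model: ProfileHMM,
) -> Contig:
    """Fuse left path + seed + right path into one contig (no duplicated
    seed bases) and rescore it under the forward model."""
    L = fwd_model.L
    seed_nt = starting.nt_kmer
    seed_aa = translate(seed_nt)
    left_codons = [st.codon for st in left.steps[1:] if st.codon]
    right_codons = [st.codon for st in right.steps[1:] if st.codon]
    nt = "".join(reversed(left_codons)) + seed_nt + "".join(right_codons)

    seed_path = [
        ("M", j, a)
        for j, a in zip(
            range(starting.model_column_first, starting.model_column_last + 1), seed_aa
        )
    ]
    right_path = [
        (st.vertex.state, st.vertex.column,
         translate_codon(st.codon) if st.codon else None)
        for st in right.steps[1:]
    ]
    path = mirror_left_steps(left.steps, L) + seed_path + right_path
    col_aa = {j: aa for s, j, aa in path if s == "M"}
    cols = [j for s, j, _ in path if s in ("M", "D")]
    span = (min(cols), max(cols))
    raw_nats = rescore_state_path(path, fwd_model)
    cid = f"{starting.gene}|c{starting.model_column_first}|{starting.nt_kmer}"
    return Contig(
        id=cid,
        gene=starting.gene,
        nt=nt,
        aa=translate(nt),
        bits=bit_score(raw_nats),
        raw_nats=raw_nats,
        model_span=span,
        col_aa=col_aa,
        state_path=path,
        partial=left.partial or right.partial,
        seed_id=starting.read_id,
    )


def assemble_gene(
    starting: StartingKmer,
    fwd_model: ProfileHMM,
    rev_model: ProfileHMM,
    counter: KmerCounter,
    *,
    min_count: int = 1,
    prune: Optional[int] = 20,
    caches: Optional[tuple[dict, dict]] = None,
    heuristics: Optional[tuple[dict, dict]] = None,
    stats: Optional[dict] = None,
) -> Contig:
    """Assemble one best contig from a starting kmer.

    The right search runs the forward model from the seed's last-residue
    column; the left search runs the reversed model from the mirrored
    first-residue column.  Seed emissions are credited only at rescoring,
    keeping the two directional searches independent.
    """
    L = fwd_model.L
    fwd_h, rev_h = heuristics if heuristics is not None else (None, None)
    right_cache, left_cache = caches if caches is not None else (None, None)

    right_start = Vertex(starting.nt_kmer, starting.model_column_last, "M")
    if right_start.column >= L:
        right = trivial_result(right_start)
    else:
        right = astar_search(
            right_start, fwd_model, counter,
            min_count=min_count, prune=prune, cache=right_cache,
            direction="right", heuristic=fwd_h,
        )

    rev_col = L - starting.model_column_first + 1
    left_start = Vertex(starting.nt_kmer, rev_col, "M")
    if rev_col >= L:
        left = trivial_result(left_start)
    else:
        left = astar_search(
            left_start, rev_model, counter,
            min_count=min_count, prune=prune, cache=left_cache,
            direction="left", heuristic=rev_h,
        )
    if stats is not None:
        stats["opened"] = stats.get("opened", 0) + left.opened + right.opened
        stats["searches"] = stats.get("searches", 0) + 2
    return combine_results(starting, left, right, fwd_model)
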