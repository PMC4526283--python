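"""Independent brute-force oracles for the search tests.

These enumerate paths by depth-first search over the same vertex expansion
the assembler uses, entirely bypassing A*, priority queues, caching and
pruning, so they can confirm (or refute) the searched optimum.  Indel
(insert/delete) events per path are capped where noted: every such event
carries a strongly negative weight, so optimal paths essentially never use
more than a couple, and the cap is what keeps exhaustive enumeration
tractable.  Tests additionally assert the A* result itself respects the
cap, which makes the capped comparison sound.
"""

from __future__ import annotations

import math

from hmmasm.cag_search import Vertex, successors
from hmmasm.kpaths import _nt_kmers


class PathExplosion(RuntimeError):
    pass


def enumerate_paths(
    start,
    model,
    counter,
    min_count: int = 1,
    max_indels: int | None = 2,
    max_paths: int = 400_000,
):
    """All simple start-to-goal paths as (modified, raw, vertices, codons).

    Also returns, per visited vertex, the best modified-score completion to
    the goal observed over the enumerated paths (for admissibility audits).
    """
    L = model.L
    out: list[tuple[float, float, tuple, list]] = []
    completion: dict[Vertex, float] = {}
    succ_cache: dict[Vertex, list] = {}

    def expand(v):
        if v not in succ_cache:
            succ_cache[v] = successors(v, model, counter, min_count)
        return succ_cache[v]

    def dfs(v, visited, mods, raws, verts, codons, indels):
        if v.column == L and v.state in ("M", "D"):
            if len(out) >= max_paths:
                raise PathExplosion(f"more than {max_paths} paths")
            out.append((sum(mods), sum(raws), tuple(verts), list(codons)))
            acc = 0.0
            for i in range(len(verts) - 1, -1, -1):
                u = verts[i]
                if acc > completion.get(u, -math.inf):
                    completion[u] = acc
                if i > 0:
                    acc += mods[i]
            return
        for nv, codon, w_mod, w_raw in expand(v):
            extra = 1 if nv.state in ("I", "D") else 0
            if max_indels is not None and indels + extra > max_indels:
                continue
            if nv in visited:
                continue
            visited.add(nv)
            verts.append(nv)
            mods.append(w_mod)
            raws.append(w_raw)
            codons.append(codon)
            dfs(nv, visited, mods, raws, verts, codons, indels + extra)
            visited.discard(nv)
            verts.pop()
            mods.pop()
            raws.pop()
            codons.pop()

    dfs(start, {start}, [0.0], [0.0], [start], [], 0)
    return out, completion


def indel_count(result) -> int:
    """Insert/delete events on an A* search result's path."""
    return sum(1 for s in result.steps[1:] if s.vertex.state in ("I", "D"))


def ranked_reference(paths, start_kmer: str, k: int, K: int):
    """Greedy new-edge/new-kmer filtering of enumerated paths, highest
    modified score first with the implementation's tie-break (nucleotide
    sequence, then vertex tuple): the reference for Yen's K paths."""

    def to_nt(codons):
        return start_kmer + "".join(c for c in codons if c)

    items = sorted(
        ((m, r, v, to_nt(c)) for m, r, v, c in paths),
        key=lambda t: (-t[0], t[3], t[2]),
    )
    accepted = []
    edges: set = set()
    kmers: set = set()
    for mod, raw, verts, nt in items:
        p_edges = {(verts[i], verts[i + 1]) for i in range(len(verts) - 1)}
        p_kmers = _nt_kmers(nt, k)
        if not accepted or ((p_edges - edges) and (p_kmers - kmers)):
            accepted.append((mod, raw, nt))
            edges |= p_edges
            kmers |= p_kmers
        if len(accepted) >= K:
            break
    return accepted
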