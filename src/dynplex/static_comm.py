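"""Static plex-percolation communities within one graph.

Maximal k-plexes are aggregated into (possibly overlapping) communities:
two plexes belong to the same community when connected by a chain of
pairwise vertex overlaps of at least ``m - 1`` vertices, i.e. when one plex
can be "walked" to the other changing at most one vertex at a time.  The
plex-overlap graph is never materialized; only its connected components
are exposed.  With k = 1 this reduces to classic clique percolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .graphs import CommunityAssignment, Edge
from .plexes import Plex, PlexParams, enumerate_maximal_kplexes


def plex_overlap(a: Plex, b: Plex) -> int:
    """Number of vertices common to two plexes."""
    return len(a.members & b.members)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass(frozen=True)
class PlexOverlapComponents:
    """Connected components of the implicit plex-overlap graph."""

    plexes: tuple[Plex, ...]
    component_of: tuple[int, ...]  # component index per plex, 0-based dense

    def component_plexes(self) -> list[list[Plex]]:
        n_comp = max(self.component_of, default=-1) + 1
        out: list[list[Plex]] = [[] for _ in range(n_comp)]
        for plex, c in zip(self.plexes, self.component_of):
            out[c].append(plex)
        return out


def percolate_plexes(
    plexes: Sequence[Plex], overlap_threshold: int
) -> PlexOverlapComponents:
    """Group plexes by transitive >=threshold vertex overlap.

    Only plex pairs sharing at least one vertex are compared (an inverted
    vertex->plex index), so the quadratic all-pairs comparison is avoided
    on disjoint structure.
    """
    uf = _UnionFind(len(plexes))
    by_vertex: dict[int, list[int]] = {}
    for i, p in enumerate(plexes):
        for v in p.members:
            by_vertex.setdefault(v, []).append(i)
    seen_pairs: set[tuple[int, int]] = set()
    for idx_list in by_vertex.values():
        for a_pos in range(len(idx_list)):
            i = idx_list[a_pos]
            for j in idx_list[a_pos + 1:]:
                pair = (i, j)
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                if plex_overlap(plexes[i], plexes[j]) >= overlap_threshold:
                    uf.union(i, j)
    roots: dict[int, int] = {}
    comp = []
    for i in range(len(plexes)):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots)
        comp.append(roots[r])
    return PlexOverlapComponents(tuple(plexes), tuple(comp))


def plex_internal_edges(plex: Plex, edges: Iterable[Edge]) -> set[Edge]:
    """Graph edges with both endpoints inside the plex."""
    mem = plex.members
    return {e for e in edges if e[0] in mem and e[1] in mem}


def static_communities(
    node_count: int,
    edges: Iterable[Edge],
    params: PlexParams,
    layer: int = 0,
) -> CommunityAssignment:
    """One-layer community assignment by plex percolation.

    Each connected component of the plex-overlap relation becomes a
    community; its member vertices and all plex-internal edges receive the
    community label.  Vertices covered by no plex receive no label.
    """
    edges = list(edges)
    plexes = enumerate_maximal_kplexes(node_count, edges, params)
    comps = percolate_plexes(plexes, params.m - 1)
    out = CommunityAssignment()
    for cid, group in enumerate(comps.component_plexes()):
        for plex in group:
            for v in plex.members:
                out.add_vertex(layer, v, cid)
            for e in plex_internal_edges(plex, edges):
                out.add_edge(layer, e, cid)
    return out.relabeled_canonical()
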