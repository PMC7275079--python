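"""DynComm: dynamic plex-percolation communities across time layers.

For every pair of adjacent layers an *enhanced bi-slice graph* on ``2p``
vertices is built: copies of both layers' edges (*observed*), an edge from
each vertex to its mature self in the next layer (*self* edges), and, for
every edge present in both layers, the mirrored cross pair
``u_t—v_{t+1}``, ``v_t—u_{t+1}`` (*railroad tracks*).  Maximal k-plexes
percolated inside each bi-slice let communities walk across time; label
propagation forward and backward in time then stitches slice and bi-slice
fragments into dynamic communities, each carrying a single id over its
whole extent.

Two modes are provided.  *Exact* mode percolates plexes inside every
bi-slice.  *Heuristic* mode (the fast approximation used for large
recordings) links per-slice communities at adjacent times directly by
vertex overlap, optionally anchored to an edge shared by both layers; it
reproduces the exact result except on m-cycles matched with isomorphic
motifs (e.g. an hourglass with a square).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .graphs import CommunityAssignment, Edge, LayeredGraph
from .plexes import (
    DEFAULT_MAX_NODES,
    Plex,
    PlexParams,
    enumerate_maximal_kplexes,
)
from .static_comm import percolate_plexes, static_communities


@dataclass(frozen=True)
class BisliceGraph:
    """Enhanced two-layer graph on 2p vertices.

    Bi-slice vertex ids: ``v`` is vertex v at the earlier layer, ``p + v``
    the same vertex at the later layer.
    """

    node_count: int  # p, per side
    observed_t: frozenset[Edge]
    observed_t1: frozenset[Edge]

    @property
    def persistent_edges(self) -> frozenset[Edge]:
        return self.observed_t & self.observed_t1

    def self_edges(self) -> list[tuple[int, int]]:
        p = self.node_count
        return [(v, p + v) for v in range(p)]

    def railroad_edges(self) -> list[tuple[int, int]]:
        p = self.node_count
        out = []
        for u, v in sorted(self.persistent_edges):
            out.append((u, p + v))
            out.append((v, p + u))
        return out

    def all_edges(self) -> list[tuple[int, int]]:
        p = self.node_count
        edges = [e for e in sorted(self.observed_t)]
        edges += [(p + u, p + v) for u, v in sorted(self.observed_t1)]
        edges += self.self_edges()
        edges += self.railroad_edges()
        return edges


def build_bislice(
    node_count: int, edges_t: Iterable[Edge], edges_t1: Iterable[Edge]
) -> BisliceGraph:
    return BisliceGraph(
        node_count=node_count,
        observed_t=frozenset(edges_t),
        observed_t1=frozenset(edges_t1),
    )


def admissible_bislice_plexes(
    bislice: BisliceGraph,
    params: PlexParams,
    cross_slice_admissibility: bool = True,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> list[Plex]:
    """Maximal k-plexes of the bi-slice, filtered for admissible time travel.

    A plex with vertices on both sides must contain at least one railroad
    edge: railroads exist only for edges persisting across both layers, so
    cross-time movement is anchored to shared observed structure and self
    edges alone can never bridge two slices.  Single-side plexes pass
    unfiltered.  For ``m - k >= 2`` the filter is essentially vacuous (the
    degree arithmetic forces railroads into any spanning plex); it is what
    keeps the over-permissive regime ``m - k <= 1`` honest.
    """
    p = bislice.node_count
    plexes = enumerate_maximal_kplexes(2 * p, bislice.all_edges(), params, max_nodes)
    if not cross_slice_admissibility:
        return plexes
    rails = {frozenset(rr) for rr in bislice.railroad_edges()}
    out = []
    for plex in plexes:
        sides = {v >= p for v in plex.members}
        if len(sides) < 2:
            out.append(plex)
            continue
        mem = plex.members
        if any(a in mem and b in mem for a, b in (tuple(r) for r in rails)):
            out.append(plex)
    return out


@dataclass(frozen=True)
class DppmConfig:
    params: PlexParams
    mode: Literal["exact", "heuristic"] = "exact"
    heuristic_overlap_strict: bool = True
    heuristic_requires_shared_edge: bool = True
    cross_slice_admissibility: bool = True
    max_nodes: int = DEFAULT_MAX_NODES


@dataclass
class Fragment:
    """A provisional community piece: labeled vertices and edges per layer."""

    vertices: dict[int, set[int]] = field(default_factory=dict)
    edges: dict[int, set[Edge]] = field(default_factory=dict)

    def add_vertex(self, t: int, v: int) -> None:
        self.vertices.setdefault(t, set()).add(v)

    def add_edge(self, t: int, e: Edge) -> None:
        self.edges.setdefault(t, set()).add(e)

    def layers(self) -> set[int]:
        return set(self.vertices) | set(self.edges)


def _fragments_from_assignment(assignment: CommunityAssignment) -> list[Fragment]:
    frags: dict[int, Fragment] = {}
    for (t, v), ids in assignment.vertex_labels.items():
        for cid in ids:
            frags.setdefault(cid, Fragment()).add_vertex(t, v)
    for (t, e), ids in assignment.edge_labels.items():
        for cid in ids:
            frags.setdefault(cid, Fragment()).add_edge(t, e)
    return [frags[c] for c in sorted(frags)]


def _bislice_fragments(
    bislice: BisliceGraph, t: int, config: DppmConfig
) -> list[Fragment]:
    """Percolated admissible plexes of one bi-slice, mapped back to layers."""
    p = bislice.node_count
    plexes = admissible_bislice_plexes(
        bislice, config.params, config.cross_slice_admissibility, config.max_nodes
    )
    comps = percolate_plexes(plexes, config.params.m - 1)
    obs_t = bislice.observed_t
    obs_t1 = bislice.observed_t1
    out = []
    for group in comps.component_plexes():
        frag = Fragment()
        for plex in group:
            side_t = {v for v in plex.members if v < p}
            side_t1 = {v - p for v in plex.members if v >= p}
            for v in side_t:
                frag.add_vertex(t, v)
            for v in side_t1:
                frag.add_vertex(t + 1, v)
            for e in obs_t:
                if e[0] in side_t and e[1] in side_t:
                    frag.add_edge(t, e)
            for e in obs_t1:
                if e[0] in side_t1 and e[1] in side_t1:
                    frag.add_edge(t + 1, e)
        out.append(frag)
    return out


def propagate_labels(fragments: Sequence[Fragment], params: PlexParams) -> CommunityAssignment:
    """Merge fragments to a fixed point and emit one id per dynamic community.

    Two fragments belong to the same dynamic community iff they are linked
    by a chain of pairwise merges, where a pair merges when, at some common
    layer, it shares a labeled observed edge or at least ``m - 1`` labeled
    vertices.  Union-find computes the transitive closure directly, so the
    result is the fixed point of the merge relation, idempotent, and
    independent of the order fragments are supplied in.
    """
    from .static_comm import _UnionFind

    uf = _UnionFind(len(fragments))
    by_layer: dict[int, list[int]] = {}
    for i, frag in enumerate(fragments):
        for t in frag.layers():
            by_layer.setdefault(t, []).append(i)
    thr = params.m - 1
    for t, idx in sorted(by_layer.items()):
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            fi = fragments[i]
            vi = fi.vertices.get(t, set())
            ei = fi.edges.get(t, set())
            for j in idx[a_pos + 1:]:
                if uf.find(i) == uf.find(j):
                    continue
                fj = fragments[j]
                if ei & fj.edges.get(t, set()):
                    uf.union(i, j)
                elif len(vi & fj.vertices.get(t, set())) >= thr:
                    uf.union(i, j)
    out = CommunityAssignment()
    root_ids: dict[int, int] = {}
    for i, frag in enumerate(fragments):
        r = uf.find(i)
        cid = root_ids.setdefault(r, len(root_ids))
        for t, vs in frag.vertices.items():
            for v in vs:
                out.add_vertex(t, v, cid)
        for t, es in frag.edges.items():
            for e in es:
                out.add_edge(t, e, cid)
    return out.relabeled_canonical()


def dppm(graph: LayeredGraph, config: DppmConfig) -> CommunityAssignment:
    """Dynamic plex percolation over a layered graph.

    Exact mode: per-slice percolation, per-bi-slice percolation over
    admissible plexes, then label propagation to a fixed point.  Heuristic
    mode: per-slice percolation followed by cross-time linking of slice
    communities by vertex overlap (optionally edge-anchored).
    """
    params = config.params
    if params.degenerate and not config.cross_slice_admissibility:
        warnings.warn(
            f"DPPM ({params.m},{params.k}) with m-k<=1 and cross-slice "
            "admissibility disabled is known to over-merge: self edges alone "
            "bridge slices",
            stacklevel=2,
        )
    slice_frags: list[Fragment] = []
    per_slice: list[CommunityAssignment] = []
    for t in range(graph.layer_count):
        assignment = static_communities(
            graph.node_count, graph.layers[t], params, layer=t
        )
        per_slice.append(assignment)
        slice_frags.extend(_fragments_from_assignment(assignment))

    if config.mode == "exact":
        fragments = list(slice_frags)
        for t in range(graph.layer_count - 1):
            bislice = build_bislice(
                graph.node_count, graph.layers[t], graph.layers[t + 1]
            )
            fragments.extend(_bislice_fragments(bislice, t, config))
        return propagate_labels(fragments, params)

    if config.mode != "heuristic":
        raise ValueError(f"unknown DPPM mode {config.mode!r}")
    return _heuristic_link(graph, slice_frags, config)


def _heuristic_link(
    graph: LayeredGraph, slice_frags: list[Fragment], config: DppmConfig
) -> CommunityAssignment:
    from .static_comm import _UnionFind

    params = config.params
    thr = params.m - 1
    uf = _UnionFind(len(slice_frags))
    by_layer: dict[int, list[int]] = {}
    for i, frag in enumerate(slice_frags):
        (t,) = frag.layers()  # slice fragments live on exactly one layer
        by_layer.setdefault(t, []).append(i)
    for t in range(graph.layer_count - 1):
        persistent = graph.layers[t] & graph.layers[t + 1]
        for i in by_layer.get(t, []):
            fi = slice_frags[i]
            vi = fi.vertices.get(t, set())
            ei = fi.edges.get(t, set()) & persistent
            for j in by_layer.get(t + 1, []):
                fj = slice_frags[j]
                ov = len(vi & fj.vertices.get(t + 1, set()))
                if config.heuristic_overlap_strict:
                    if ov <= thr:
                        continue
                elif ov < thr:
                    continue
                if config.heuristic_requires_shared_edge:
                    if not (ei & fj.edges.get(t + 1, set())):
                        continue
                uf.union(i, j)
    out = CommunityAssignment()
    root_ids: dict[int, int] = {}
    for i, frag in enumerate(slice_frags):
        r = uf.find(i)
        cid = root_ids.setdefault(r, len(root_ids))
        for t, vs in frag.vertices.items():
            for v in vs:
                out.add_vertex(t, v, cid)
        for t, es in frag.edges.items():
            for e in es:
                out.add_edge(t, e, cid)
    return out.relabeled_canonical()


def community_count(assignment: CommunityAssignment) -> int:
    return len(assignment.community_ids())
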