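"""Predicate and exact enumeration of maximal k-plexes.

A k-plex of size ``n`` is a vertex subset ``S`` of an undirected graph in
which every member is adjacent to at least ``n - k`` other members, i.e.
each vertex may miss at most ``k - 1`` of the others (itself included in
the ``k`` allowance).  A 1-plex is a clique.  k-plexes are hereditary:
every subset of a k-plex is a k-plex, which is what makes a recursive
branch-and-bound enumeration (in the Bron-Kerbosch family) complete.

The exact enumerator is the normative default.  The clique-first shortcut
(`enumerate_with_clique_first_shortcut`) finds maximal cliques first and
only searches for plexes among clique-free vertices; it is faster but can
miss maximal plexes that straddle a clique, so it is opt-in and labeled
approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

Edge = tuple[int, int]

#: Exact enumeration is refused above this vertex count unless overridden:
#: worst-case cost is exponential in the vertex count.
DEFAULT_MAX_NODES = 512


@dataclass(frozen=True)
class PlexParams:
    """Plex size floor ``m`` and order ``k`` (max missing neighbors + 1)."""

    m: int
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m <= self.k:
            raise ValueError(f"m must exceed k (got m={self.m}, k={self.k})")

    @property
    def degenerate(self) -> bool:
        """True in the over-permissive regime ``m - k <= 1``.

        There a plex may contain a vertex attached by a single edge, so
        cross-time self-edges alone can bridge otherwise unrelated slices;
        callers walking plexes across time must filter such bridges.
        """
        return self.m - self.k <= 1


@dataclass(frozen=True)
class Plex:
    """A maximal k-plex: its member vertex set (host graph kept by caller)."""

    members: frozenset[int]

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[int, ...]:
        return tuple(sorted(self.members))


def _adjacency_masks(node_count: int, edges: Iterable[Edge]) -> list[int]:
    adj = [0] * node_count
    for u, v in edges:
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    return adj


def is_kplex(edges: Iterable[Edge], subset: Iterable[int], k: int) -> bool:
    """True iff every vertex of ``subset`` has >= |subset| - k neighbors inside it."""
    nodes = set(subset)
    if not nodes:
        raise ValueError("subset must be non-empty")
    need = len(nodes) - k
    if need <= 0:
        return True
    deg = {v: 0 for v in nodes}
    for u, v in edges:
        if u in nodes and v in nodes:
            deg[u] += 1
            deg[v] += 1
    return min(deg.values()) >= need


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def enumerate_maximal_kplexes(
    node_count: int,
    edges: Iterable[Edge],
    params: PlexParams,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> list[Plex]:
    """Enumerate all inclusion-maximal k-plexes with at least ``m`` vertices.

    Exact: output equals brute-force enumeration over all vertex subsets.
    Deterministic: plexes are returned sorted by member list.
    """
    if node_count > max_nodes:
        raise ValueError(
            f"exact plex enumeration refused for {node_count} > {max_nodes} "
            f"vertices (worst case is exponential); raise max_nodes to force"
        )
    m, k = params.m, params.k
    adj = _adjacency_masks(node_count, edges)
    results: list[frozenset[int]] = []

    # A k-plex whose smallest connected part has m-k+1 vertices cannot span
    # two graph components when 2*(m-k+1) > m, so the search may run per
    # component.  (For m - k <= 1 disconnected plexes exist, e.g. two
    # disjoint edges form a 3-plex of size 4, and we search the whole graph.)
    decomposable = 2 * (params.m - params.k + 1) > params.m
    # k-plexes of size >= 2k-1 have induced diameter <= 2 (Seidman-Foster),
    # so when m >= 2k-1 any candidate at host-graph distance > 2 from a
    # chosen member can never complete a reportable plex.
    use_dist2 = m >= 2 * k - 1
    if use_dist2:
        n2 = []
        for v in range(node_count):
            reach = adj[v] | (1 << v)
            for w in _bits(adj[v]):
                reach |= adj[w]
            n2.append(reach)

    def can_add(
        s_list: list[int], s_mask: int, deg: dict[int, int], v: int
    ) -> bool:
        need = len(s_list) + 1 - k
        if (adj[v] & s_mask).bit_count() < need:
            return False
        for u in s_list:
            if deg[u] + ((adj[u] >> v) & 1) < need:
                return False
        return True

    def expand(
        s_list: list[int], s_mask: int, deg: dict[int, int], cand: int, excl: int
    ) -> None:
        while cand:
            if len(s_list) + cand.bit_count() < m:
                return
            # domination prune: a compatible excluded vertex adjacent to
            # every current and future member makes all extensions
            # non-maximal
            probe = s_mask | cand
            for u in _bits(excl):
                if probe & ~adj[u] == 0:
                    return
            v = (cand & -cand).bit_length() - 1

            # branch: include v
            s2 = s_list + [v]
            mask2 = s_mask | (1 << v)
            deg2 = {u: deg[u] + ((adj[u] >> v) & 1) for u in s_list}
            deg2[v] = (adj[v] & s_mask).bit_count()
            rest = cand & ~(1 << v)
            excl_pool = excl
            if use_dist2:
                rest &= n2[v]
                excl_pool &= n2[v]
            cand2 = 0
            for u in _bits(rest):
                if can_add(s2, mask2, deg2, u):
                    cand2 |= 1 << u
            excl2 = 0
            for u in _bits(excl_pool):
                if can_add(s2, mask2, deg2, u):
                    excl2 |= 1 << u
            expand(s2, mask2, deg2, cand2, excl2)

            # continue with v excluded
            cand &= ~(1 << v)
            excl |= 1 << v
        if excl == 0 and len(s_list) >= m:
            results.append(frozenset(s_list))

    if decomposable:
        seen = 0
        for root in range(node_count):
            if (seen >> root) & 1:
                continue
            comp = 1 << root
            frontier = adj[root]
            while frontier & ~comp:
                comp |= frontier
                nxt = 0
                for w in _bits(frontier):
                    nxt |= adj[w]
                frontier = nxt & ~comp
            seen |= comp
            if comp.bit_count() >= m:
                expand([], 0, {}, comp, 0)
    else:
        expand([], 0, {}, (1 << node_count) - 1, 0)

    results.sort(key=lambda s: tuple(sorted(s)))
    return [Plex(s) for s in results]


def brute_force_maximal_kplexes(
    node_count: int, edges: Iterable[Edge], params: PlexParams
) -> list[Plex]:
    """Independent oracle: exhaustive scan of all 2^p vertex subsets.

    Only usable for tiny graphs; kept as the reference the fast enumerator
    is validated against.
    """
    edges = list(edges)
    adj = _adjacency_masks(node_count, edges)

    def plex_mask(mask: int) -> bool:
        n = mask.bit_count()
        need = n - params.k
        if need <= 0:
            return True
        for v in _bits(mask):
            if (adj[v] & mask).bit_count() < need:
                return False
        return True

    plex_masks = [mask for mask in range(1, 1 << node_count) if plex_mask(mask)]
    out = []
    for mask in plex_masks:
        if mask.bit_count() < params.m:
            continue
        maximal = True
        for v in range(node_count):
            if not (mask >> v) & 1 and plex_mask(mask | (1 << v)):
                maximal = False
                break
        if maximal:
            out.append(Plex(frozenset(_bits(mask))))
    out.sort(key=lambda p: p.sorted_members())
    return out


def enumerate_with_clique_first_shortcut(
    node_count: int,
    edges: Iterable[Edge],
    params: PlexParams,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> list[Plex]:
    """Accelerated approximate variant: maximal cliques first, then plexes
    among the vertices not covered by any large clique.

    Can omit maximal plexes overlapping cliques; callers must opt in
    explicitly (the driver never uses it by default).
    """
    edges = list(edges)
    g = nx.Graph()
    g.add_nodes_from(range(node_count))
    g.add_edges_from(edges)
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= params.m]
    covered: set[int] = set()
    for c in cliques:
        covered |= c
    remaining = [v for v in range(node_count) if v not in covered]
    remap = {v: i for i, v in enumerate(remaining)}
    sub_edges = [
        (remap[u], remap[v]) for u, v in edges if u in remap and v in remap
    ]
    extra = enumerate_maximal_kplexes(len(remaining), sub_edges, params, max_nodes)
    inv = {i: v for v, i in remap.items()}
    out = {frozenset(c) for c in cliques}
    out |= {frozenset(inv[i] for i in p.members) for p in extra}
    return [Plex(s) for s in sorted(out, key=lambda s: tuple(sorted(s)))]


def covered_vertices(plexes: Sequence[Plex]) -> set[int]:
    out: set[int] = set()
    for p in plexes:
        out |= p.members
    return out
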