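"""Data model and I/O for layered binary networks and community labelings.

A *layered graph* is a sequence of simple undirected graphs on a common
vertex set ``{0, ..., p-1}``, one graph per time layer.  Layers and node ids
are 0-based throughout; edges are stored canonically as ``(u, v)`` with
``u < v``.  Empty layers are legal: simulated recordings include intervals
with no organized structure.

Community labelings are multi-label: a vertex or an edge at a given layer
may belong to several overlapping communities.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Edge = tuple[int, int]


def canonical_edge(u: int, v: int) -> Edge:
    """Return the pair ordered ``u < v``; self-loops are rejected."""
    if u == v:
        raise ValueError(f"self-loop on node {u}")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class LayeredGraph:
    """A sequence of simple undirected graphs sharing one vertex set.

    Parameters
    ----------
    node_count:
        Number of vertices ``p``; every layer's vertex set is ``{0..p-1}``.
    layers:
        One frozen edge set per time layer, each edge stored as ``(u, v)``
        with ``u < v``.
    """

    node_count: int
    layers: tuple[frozenset[Edge], ...]

    def __post_init__(self) -> None:
        if self.node_count <= 0:
            raise ValueError("node_count must be positive")
        for t, edges in enumerate(self.layers):
            for u, v in edges:
                if not (0 <= u < v < self.node_count):
                    raise ValueError(
                        f"edge ({u},{v}) at layer {t} outside vertex range "
                        f"or not canonically ordered"
                    )

    @property
    def layer_count(self) -> int:
        return len(self.layers)

    @classmethod
    def from_edge_lists(
        cls, node_count: int, layers: Sequence[Iterable[tuple[int, int]]]
    ) -> "LayeredGraph":
        """Build from arbitrary (possibly unordered, duplicated) pair lists."""
        canon = tuple(
            frozenset(canonical_edge(u, v) for u, v in layer) for layer in layers
        )
        return cls(node_count, canon)

    def reversed_time(self) -> "LayeredGraph":
        return LayeredGraph(self.node_count, tuple(reversed(self.layers)))

    def adjacency(self, t: int) -> list[set[int]]:
        """Neighbor sets of layer ``t``."""
        adj: list[set[int]] = [set() for _ in range(self.node_count)]
        for u, v in self.layers[t]:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def degree(layer_edges: Iterable[Edge], v: int) -> int:
    """Degree of ``v`` in one layer's edge set."""
    return sum(1 for e in layer_edges if v in e)


def induced_min_degree(layer_edges: Iterable[Edge], subset: Iterable[int]) -> int:
    """Minimum, over v in ``subset``, of v's neighbor count inside ``subset``.

    This is the quantity the k-plex condition bounds from below: a subset S
    is a k-plex iff ``induced_min_degree(G, S) >= |S| - k``.
    """
    nodes = set(subset)
    if not nodes:
        raise ValueError("subset must be non-empty")
    deg = {v: 0 for v in nodes}
    for u, v in layer_edges:
        if u in nodes and v in nodes:
            deg[u] += 1
            deg[v] += 1
    return min(deg.values())


@dataclass
class CommunityAssignment:
    """Multi-label community assignment over (layer, node) and (layer, edge).

    ``vertex_labels[(t, v)]`` and ``edge_labels[(t, (u, v))]`` are sets of
    opaque integer community ids, unique across the whole dynamic analysis.
    """

    vertex_labels: dict[tuple[int, int], set[int]] = field(default_factory=dict)
    edge_labels: dict[tuple[int, Edge], set[int]] = field(default_factory=dict)

    def add_vertex(self, t: int, v: int, cid: int) -> None:
        self.vertex_labels.setdefault((t, v), set()).add(cid)

    def add_edge(self, t: int, e: Edge, cid: int) -> None:
        self.edge_labels.setdefault((t, e), set()).add(cid)

    def community_ids(self) -> set[int]:
        ids: set[int] = set()
        for s in self.vertex_labels.values():
            ids |= s
        for s in self.edge_labels.values():
            ids |= s
        return ids

    def members(self, cid: int) -> dict[int, set[int]]:
        """Per-layer member node sets of one community."""
        out: dict[int, set[int]] = {}
        for (t, v), ids in self.vertex_labels.items():
            if cid in ids:
                out.setdefault(t, set()).add(v)
        return out

    def views(self) -> list["CommunityView"]:
        return [
            CommunityView.from_members(cid, self.members(cid))
            for cid in sorted(self.community_ids())
        ]

    def relabeled_canonical(self) -> "CommunityAssignment":
        """Reassign ids in first-appearance order by (layer, smallest node).

        Makes outputs deterministic given the set of communities, independent
        of the internal order the detection algorithm produced them in.
        """
        keys = {}
        for cid in self.community_ids():
            mem = self.members(cid)
            if mem:
                t0 = min(mem)
                keys[cid] = (t0, min(mem[t0]), sorted(mem.items()))
            else:  # community present only on edges (does not happen in practice)
                keys[cid] = (10**9, 10**9, [])
        order = sorted(keys, key=lambda c: keys[c])
        remap = {old: new for new, old in enumerate(order)}
        out = CommunityAssignment()
        for (t, v), ids in self.vertex_labels.items():
            for cid in ids:
                out.add_vertex(t, v, remap[cid])
        for (t, e), ids in self.edge_labels.items():
            for cid in ids:
                out.add_edge(t, e, remap[cid])
        return out


@dataclass(frozen=True)
class CommunityView:
    """Materialization of one community for statistics."""

    id: int
    members_by_layer: tuple[tuple[int, frozenset[int]], ...]
    first_layer: int
    last_layer: int

    @classmethod
    def from_members(cls, cid: int, members: Mapping[int, set[int]]) -> "CommunityView":
        if not members:
            raise ValueError(f"community {cid} has empty extent")
        layers = sorted(members)
        return cls(
            id=cid,
            members_by_layer=tuple((t, frozenset(members[t])) for t in layers),
            first_layer=layers[0],
            last_layer=layers[-1],
        )

    @property
    def extent(self) -> int:
        """Total number of (node, layer) elements."""
        return sum(len(m) for _, m in self.members_by_layer)

    @property
    def max_size(self) -> int:
        return max(len(m) for _, m in self.members_by_layer)


# ---------------------------------------------------------------------------
# I/O: layered edge-list TSV and communities TSV
# ---------------------------------------------------------------------------

_EDGELIST_HEADER = "layer\tu\tv"
_COMM_HEADER = "layer\tnode\tcommunity_id"


def read_layered_edgelist(source) -> LayeredGraph:
    """Read a layered edge-list TSV (``layer\\tu\\tv`` rows).

    Layers need not be sorted; missing intermediate layers become empty
    layers.  ``p`` defaults to 1 + max node id and may be overridden by a
    ``#nodes=p`` comment.  Node ids and layers are 0-based.
    """
    close = False
    if isinstance(source, (str, bytes, os.PathLike)):
        fh = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        forced_p = None
        forced_layers = None
        rows: list[tuple[int, int, int]] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if tok.startswith("nodes="):
                        forced_p = int(tok[6:])
                    elif tok.startswith("layers="):
                        forced_layers = int(tok[7:])
                continue
            if line.lower().startswith("layer"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(parts)}")
            t, u, v = (int(x) for x in parts)
            if t < 0 or u < 0 or v < 0:
                raise ValueError(f"line {lineno}: negative layer or node id")
            if u == v:
                raise ValueError(f"line {lineno}: self-loop on node {u}")
            rows.append((t, u, v))
    finally:
        if close:
            fh.close()

    n_layers = forced_layers
    if n_layers is None:
        n_layers = 1 + max((t for t, _, _ in rows), default=-1)
    if n_layers == 0:
        n_layers = 1  # an empty file still describes one empty layer
    p = forced_p
    if p is None:
        p = 1 + max((max(u, v) for _, u, v in rows), default=0)
    layers: list[set[Edge]] = [set() for _ in range(n_layers)]
    for t, u, v in rows:
        layers[t].add(canonical_edge(u, v))
    return LayeredGraph(p, tuple(frozenset(s) for s in layers))


def write_layered_edgelist(graph: LayeredGraph, target) -> None:
    """Write the layered edge-list TSV (inverse of :func:`read_layered_edgelist`)."""
    lines = [f"# nodes={graph.node_count} layers={graph.layer_count}", _EDGELIST_HEADER]
    for t, edges in enumerate(graph.layers):
        for u, v in sorted(edges):
            lines.append(f"{t}\t{u}\t{v}")
    _write_text(target, "\n".join(lines) + "\n")


def write_communities(assignment: CommunityAssignment, target) -> None:
    """Write vertex memberships as TSV, one row per (layer, node, id)."""
    lines = [_COMM_HEADER]
    for (t, v), ids in sorted(assignment.vertex_labels.items()):
        for cid in sorted(ids):
            lines.append(f"{t}\t{v}\t{cid}")
    _write_text(target, "\n".join(lines) + "\n")


def read_communities(source) -> CommunityAssignment:
    """Read a communities TSV back into a (vertex-label) assignment."""
    close = False
    if isinstance(source, (str, bytes, os.PathLike)):
        fh = open(source, "r", encoding="utf-8")
        close = True
    else:
        fh = source
    out = CommunityAssignment()
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("layer"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields")
            t, v, cid = (int(x) for x in parts)
            out.add_vertex(t, v, cid)
    finally:
        if close:
            fh.close()
    return out


def to_dense_array(graph: LayeredGraph):
    """Stacked 0/1 adjacency (layers x p x p) as a numpy array."""
    import numpy as np

    out = np.zeros((graph.layer_count, graph.node_count, graph.node_count), dtype=np.uint8)
    for t, edges in enumerate(graph.layers):
        for u, v in edges:
            out[t, u, v] = 1
            out[t, v, u] = 1
    return out


def from_dense_array(stack) -> LayeredGraph:
    """Inverse of :func:`to_dense_array`; symmetrizes and ignores the diagonal."""
    import numpy as np

    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("expected a layers x p x p array")
    p = stack.shape[1]
    layers = []
    for t in range(stack.shape[0]):
        iu, ju = np.nonzero(np.triu(stack[t] | stack[t].T, k=1))
        layers.append(list(zip(iu.tolist(), ju.tolist())))
    return LayeredGraph.from_edge_lists(p, layers)


def _write_text(target, text: str) -> None:
    if isinstance(target, (str, bytes, os.PathLike)):
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif isinstance(target, io.TextIOBase) or hasattr(target, "write"):
        target.write(text)
    else:
        raise TypeError(f"cannot write to {type(target)!r}")
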