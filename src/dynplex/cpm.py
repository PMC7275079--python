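"""Clique percolation baseline with across-time overlap/coin-flip linking.

Per-slice communities come from classic clique percolation (plex
percolation at k = 1: maximal cliques of size >= m chained by overlaps of
m - 1 vertices).  Across adjacent times the linking is deliberately ad
hoc, mirroring the comparison baseline: a community at t+1 that shares at
least ``link_threshold`` vertices with one or more communities at t
inherits the label of a maximal-overlap predecessor, exact ties broken by
a fair coin flip (seeded), and otherwise starts a fresh label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import CommunityAssignment, LayeredGraph
from .plexes import PlexParams
from .static_comm import static_communities


@dataclass(frozen=True)
class CpmConfig:
    m: int = 3
    seed: int = 0
    link_threshold: int = 1

    def __post_init__(self) -> None:
        if self.m < 3:
            raise ValueError("minimum clique size m must be >= 3")
        if not (1 <= self.link_threshold <= self.m - 1):
            raise ValueError("link_threshold must be in 1..m-1")


@dataclass
class _SliceCommunity:
    layer: int
    local_id: int
    global_id: int  # deterministic id of this per-slice community
    vertices: set[int]
    edges: set[tuple[int, int]]


def _slice_communities(graph: LayeredGraph, m: int) -> list[list[_SliceCommunity]]:
    """Deterministic per-slice clique-percolation communities.

    Global ids are assigned in (layer, local id) order so that they are
    identical across repetitions; only the *inherited* dynamic labels vary
    with the coin flips.
    """
    params = PlexParams(m, 1)
    out: list[list[_SliceCommunity]] = []
    counter = 0
    for t in range(graph.layer_count):
        assignment = static_communities(graph.node_count, graph.layers[t], params, t)
        comms = []
        by_id: dict[int, _SliceCommunity] = {}
        for (layer, v), ids in assignment.vertex_labels.items():
            for cid in ids:
                if cid not in by_id:
                    by_id[cid] = _SliceCommunity(t, cid, -1, set(), set())
                by_id[cid].vertices.add(v)
        for (layer, e), ids in assignment.edge_labels.items():
            for cid in ids:
                by_id[cid].edges.add(e)
        for cid in sorted(by_id):
            c = by_id[cid]
            c.global_id = counter
            counter += 1
            comms.append(c)
        out.append(comms)
    return out


def cpm(graph: LayeredGraph, config: CpmConfig) -> CommunityAssignment:
    """Dynamic communities by per-slice CPM plus coin-flip linking.

    Fully reproducible for a fixed seed.  Community ids are the dynamic
    labels: a community that inherits keeps its predecessor's label, so the
    number of distinct ids is the number of dynamic communities.
    """
    rng = np.random.default_rng(config.seed)
    slices = _slice_communities(graph, config.m)
    label: dict[int, int] = {}  # global slice-community id -> dynamic label
    for c in slices[0] if slices else []:
        label[c.global_id] = c.global_id
    for t in range(1, len(slices)):
        prev = slices[t - 1]
        for c in slices[t]:
            overlaps = [(len(c.vertices & p.vertices), p) for p in prev]
            overlaps = [(ov, p) for ov, p in overlaps if ov >= config.link_threshold]
            if not overlaps:
                label[c.global_id] = c.global_id
                continue
            best = max(ov for ov, _ in overlaps)
            candidates = sorted(
                {label[p.global_id] for ov, p in overlaps if ov == best}
            )
            if len(candidates) == 1:
                label[c.global_id] = candidates[0]
            else:
                label[c.global_id] = candidates[int(rng.integers(len(candidates)))]
    out = CommunityAssignment()
    for comms in slices:
        for c in comms:
            lab = label[c.global_id]
            for v in c.vertices:
                out.add_vertex(c.layer, v, lab)
            for e in c.edges:
                out.add_edge(c.layer, e, lab)
    return out


def cpm_label_distribution(
    graph: LayeredGraph, config: CpmConfig, reps: int
) -> dict[tuple[int, int], dict[int, float]]:
    """Empirical label-inheritance frequencies over seeded repetitions.

    Returns, per (layer, node), the fraction of repetitions in which the
    node carried each dynamic label.  The per-slice stage is deterministic,
    so labels are comparable across repetitions; only tie-break coin flips
    differ (seeds ``config.seed + r`` for r in 0..reps-1).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    counts: dict[tuple[int, int], dict[int, int]] = {}
    for r in range(reps):
        run = cpm(graph, CpmConfig(config.m, config.seed + r, config.link_threshold))
        for (t, v), ids in run.vertex_labels.items():
            slot = counts.setdefault((t, v), {})
            for cid in ids:
                slot[cid] = slot.get(cid, 0) + 1
    return {
        key: {cid: n / reps for cid, n in sorted(slot.items())}
        for key, slot in counts.items()
    }
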