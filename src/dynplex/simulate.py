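"""Synthetic benchmark generators for dynamic community detection.

Three families of inputs:

* deterministic two-layer toy fixtures (7/8/9-edge ladder) in which two
  triangles at time t evolve into one connected component at time t+1 that
  shares 0, 1 or 2 edges with time t;
* a type-II (missing-edge) noise experiment: a fixed nine-node, eight-edge
  connected template replicated over 100 layers with two uniformly chosen
  edges deleted per layer;
* four planted community-evolution scenarios (expand, contract, split,
  merge) on 64 nodes: a multilayer label matrix drives a degree-corrected
  within-block edge sampler with power-law expected degrees (exponent -2,
  degrees 3..20, zero between-block mixing).

Each layer conventionally represents a functional network inferred for a
1 s interval, so layers map one-to-one onto seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graphs import Edge, LayeredGraph, canonical_edge

#: Seconds of recording each simulated layer stands for.
LAYER_SECONDS = 1.0

#: Planted-community label; random background labels are drawn from 1..64.
PLANTED_LABEL = 0

SCENARIO_NAMES = ("expand", "contract", "split", "merge")


@dataclass(frozen=True)
class DegreeModelParams:
    """Within-block degree model: truncated power-law expected degrees."""

    powerlaw_exponent: float = -2.0
    min_degree: int = 3
    max_degree: int = 20
    mixing: float = 0.0
    max_rejections: int = 100


@dataclass
class ScenarioTruth:
    """Planted multilayer labels and the designated true community c_T(t)."""

    scenario: str
    seed: int
    label_matrix: np.ndarray  # (nodes, layers) int labels
    true_community: list[set[int]]  # per layer; empty in random intervals
    rejection_log: list[tuple[int, int, int]] = field(default_factory=list)
    # (layer, block-label, rejections) for blocks that hit the retry cap

    @property
    def node_count(self) -> int:
        return self.label_matrix.shape[0]

    @property
    def layer_count(self) -> int:
        return self.label_matrix.shape[1]


# ---------------------------------------------------------------------------
# Deterministic toy fixtures (two-layer ladder)
# ---------------------------------------------------------------------------

_TOY_LAYER0: tuple[Edge, ...] = ((0, 1), (0, 2), (1, 2), (4, 5), (4, 6), (5, 6))
_TOY_LAYER1_BASE: tuple[Edge, ...] = (
    (2, 3), (3, 4), (2, 4), (1, 3), (0, 3), (3, 5), (3, 6),
)


def toy_fixture(variant: str) -> LayeredGraph:
    """Two-layer, seven-node ladder fixture.

    Layer 0 holds two disjoint triangles {0,1,2} and {4,5,6} with node 3
    unattached.  Layer 1 is a single connected component centered on node 3
    containing the triangle {2,3,4}; the base variant shares no edge with
    layer 0, ``edges8`` adds {0,1} (one shared edge), ``edges9`` further
    adds {4,5} (two shared edges).
    """
    layer1 = list(_TOY_LAYER1_BASE)
    if variant == "edges7":
        pass
    elif variant == "edges8":
        layer1.append((0, 1))
    elif variant == "edges9":
        layer1.append((0, 1))
        layer1.append((4, 5))
    else:
        raise ValueError(f"unknown toy variant {variant!r}")
    return LayeredGraph.from_edge_lists(7, [_TOY_LAYER0, layer1])


# ---------------------------------------------------------------------------
# Edge-deletion (type-II) noise experiment
# ---------------------------------------------------------------------------

#: Default nine-node template: a double star with centers 3 and 5.
NOISE_TEMPLATE: tuple[Edge, ...] = (
    (0, 3), (1, 3), (2, 3), (3, 5), (4, 5), (5, 6), (5, 7), (5, 8),
)


def _is_connected(node_count: int, edges: Sequence[Edge]) -> bool:
    adj: dict[int, set[int]] = {v: set() for v in range(node_count)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == node_count


def noise_template_sim(
    template: Sequence[Edge] = NOISE_TEMPLATE,
    steps: int = 100,
    removals: int = 2,
    seed: int = 0,
    force: bool = False,
) -> LayeredGraph:
    """Replicate a persistent template graph with per-layer random deletions.

    Each layer is the template minus ``removals`` edges chosen uniformly
    without replacement, independently across layers.  The default template
    is a connected nine-node tree (eight edges), so every layer has six
    edges and consecutive layers share at least four.
    """
    template = tuple(canonical_edge(u, v) for u, v in template)
    p = 1 + max(max(e) for e in template)
    if not force:
        if p != 9 or len(template) != 8 or not _is_connected(p, template):
            raise ValueError(
                "template must be a connected 9-node, 8-edge graph "
                "(pass force=True to override)"
            )
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(steps):
        drop = set(rng.choice(len(template), size=removals, replace=False).tolist())
        layers.append([e for i, e in enumerate(template) if i not in drop])
    return LayeredGraph.from_edge_lists(p, layers)


# ---------------------------------------------------------------------------
# Planted community-evolution scenarios
# ---------------------------------------------------------------------------


def _scenario_schedule(name: str) -> tuple[int, list[tuple[int, list[range]]]]:
    """Interval length and, per interval, the node blocks active in it."""
    c1 = range(0, 15)
    c2 = range(15, 30)
    c3 = range(30, 45)
    if name == "split":
        return 20, [(0, []), (1, [c2]), (2, [c1, c2, c3]), (3, [c1, c3]), (4, [])]
    if name == "merge":
        return 20, [(0, []), (1, [c1, c3]), (2, [c1, c2, c3]), (3, [c2]), (4, [])]
    if name in ("expand", "contract"):
        blocks = [range(0, 15)] + [range(15 + 10 * i, 25 + 10 * i) for i in range(4)]
        sched = [(0, [])]
        for i in range(1, 6):
            sched.append((i, blocks[:i]))
        sched.append((6, []))
        return 20, sched
    raise ValueError(f"unknown scenario {name!r}")


def scenario_labels(name: str, seed: int, node_count: int = 64) -> ScenarioTruth:
    """Build the planted multilayer label matrix for one scenario.

    Active nodes carry the planted label; every other node draws an
    independent uniform label in 1..64 per layer, so transient coincidental
    groups (the background noise communities of the benchmark) can occur.
    Contract is expand with the time axis reversed.
    """
    base = "expand" if name == "contract" else name
    interval_len, schedule = _scenario_schedule(base)
    n_layers = interval_len * len(schedule)
    rng = np.random.default_rng(seed)
    labels = rng.integers(1, node_count + 1, size=(node_count, n_layers))
    truth: list[set[int]] = [set() for _ in range(n_layers)]
    for interval, blocks in schedule:
        active = sorted({v for b in blocks for v in b})
        for t in range(interval * interval_len, (interval + 1) * interval_len):
            for v in active:
                labels[v, t] = PLANTED_LABEL
            truth[t] = set(active)
    if name == "contract":
        labels = labels[:, ::-1].copy()
        truth = truth[::-1]
    return ScenarioTruth(name, seed, labels, truth)


def _draw_degrees(
    rng: np.random.Generator, size: int, params: DegreeModelParams
) -> np.ndarray:
    """Truncated discrete power-law expected degrees, capped at size-1."""
    support = np.arange(params.min_degree, params.max_degree + 1, dtype=float)
    probs = support ** params.powerlaw_exponent
    probs /= probs.sum()
    draws = rng.choice(support, size=size, p=probs)
    return np.minimum(draws, size - 1)


def sample_layer(
    labels: np.ndarray,
    params: DegreeModelParams,
    rng: np.random.Generator,
    rejection_log: list | None = None,
    layer_index: int = 0,
) -> set[Edge]:
    """Sample one layer's edges from the per-node labels.

    With zero mixing, edges appear only inside same-label groups.  Each
    group of size >= 2 gets expected degrees from the truncated power law
    and edges from a degree-corrected (Chung-Lu-style) trial: a pair (i, j)
    is an edge with probability min(1, w_i w_j / sum(w)).  A block in which
    some node ends up isolated is resampled, up to ``max_rejections``
    attempts; past the cap the best attempt so far is kept and logged.
    """
    if params.mixing != 0.0:
        raise NotImplementedError("only zero between-block mixing is modeled")
    edges: set[Edge] = set()
    groups: dict[int, list[int]] = {}
    for v, lab in enumerate(labels.tolist()):
        groups.setdefault(lab, []).append(v)
    for lab in sorted(groups):
        members = groups[lab]
        size = len(members)
        if size < 2:
            continue
        w = _draw_degrees(rng, size, params)
        total = w.sum()
        best: set[Edge] | None = None
        best_isolated = size + 1
        rejections = 0
        while True:
            probs = np.minimum(1.0, np.outer(w, w) / total)
            iu, ju = np.triu_indices(size, k=1)
            hit = rng.random(iu.shape[0]) < probs[iu, ju]
            block = {
                canonical_edge(members[i], members[j])
                for i, j in zip(iu[hit].tolist(), ju[hit].tolist())
            }
            deg = {v: 0 for v in members}
            for u, v in block:
                deg[u] += 1
                deg[v] += 1
            isolated = sum(1 for d in deg.values() if d == 0)
            if isolated < best_isolated:
                best, best_isolated = block, isolated
            if isolated == 0 or rejections >= params.max_rejections:
                break
            rejections += 1
        if best_isolated > 0 and rejection_log is not None:
            rejection_log.append((layer_index, lab, rejections))
        edges |= best if best is not None else set()
    return edges


def make_scenario(
    name: str,
    seed: int,
    params: DegreeModelParams = DegreeModelParams(),
    node_count: int = 64,
) -> tuple[LayeredGraph, ScenarioTruth]:
    """Generate one scenario realization: layered graph plus planted truth.

    Deterministic given (name, seed).  For contract, both the labels and
    the sampled layers are the exact time reversal of the expand run with
    the same seed.
    """
    base = "expand" if name == "contract" else name
    truth = scenario_labels(base, seed, node_count)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD9)))
    layers = []
    for t in range(truth.layer_count):
        layers.append(
            sample_layer(
                truth.label_matrix[:, t], params, rng,
                rejection_log=truth.rejection_log, layer_index=t,
            )
        )
    if name == "contract":
        layers = layers[::-1]
        truth = ScenarioTruth(
            "contract",
            seed,
            truth.label_matrix[:, ::-1].copy(),
            truth.true_community[::-1],
            truth.rejection_log,
        )
    graph = LayeredGraph.from_edge_lists(node_count, layers)
    return graph, truth
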