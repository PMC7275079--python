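# dynplex

Dynamic plex percolation for tracking communities in time-indexed binary
networks, with a clique-percolation baseline, planted benchmark
simulators, a cross-correlation functional-network inference front-end,
and sensitivity/specificity assessment.

## The problem

Functional networks inferred from multichannel brain voltage recordings
(e.g. ECoG during epileptic seizures) are binary graphs re-estimated every
second on a fixed electrode set.  Edges in such graphs are noisy —
false-negative (missing) edges are endemic — and the scientific questions
are about *dynamic communities*: groups of nodes that stay densely
interconnected while they expand, contract, split, or merge over time.
Classic approaches either detect communities per time slice and stitch
them with ad hoc overlap rules (clique percolation, CPM), or optimize a
multilayer modularity objective with an implicit community notion.  Both
struggle with edge noise and give ambiguous cross-time identities.

## The method

A **k-plex** of size *m* is a vertex subset S, |S| = m, in which every
member is adjacent to at least *m − k* others — a near-clique tolerating
up to *k − 1* missing neighbors per member (a 1-plex is a clique).
Communities are defined by *walking* plexes:

1. **Plex** enumerates all maximal k-plexes with ≥ *m* vertices
   (a Bron–Kerbosch-style exact backtracking enumerator).
2. **StatComm** chains plexes whose pairwise vertex overlap is ≥ *m − 1*
   into (possibly overlapping) static communities — the connected
   components of the implicit plex-overlap graph, which is never
   materialized.
3. **DynComm** builds, for each pair of adjacent layers, an enhanced
   *bi-slice* graph on 2p vertices: both layers' edges, a *self* edge
   v_t—v_{t+1} for every vertex, and mirrored *railroad* edges
   u_t—v_{t+1}, v_t—u_{t+1} for every edge present in both layers.
   Percolating plexes inside the bi-slices lets communities cross time;
   label propagation forward and backward then assigns each dynamic
   community a single id over its whole extent.

Because a plex tolerates missing neighbors, a community whose edges
flicker from layer to layer is still walked continuously — robustness to
type-II edge noise is the method's point.  A fast *heuristic* mode links
per-slice communities directly by vertex overlap (> *m − 1*), anchored to
an edge shared by both layers; it is nearly exact for the parameter
ranges used here and is the practical choice for long recordings.

## Worked example

The deterministic seven-node ladder: two triangles at time t evolve into
one connected component at t + 1 that shares 0, 1, or 2 edges with time t.
The dynamic community count must step 3 → 2 → 1 as shared edges are added,
because railroad edges (and hence cross-time plexes) only exist for edges
present in both layers:

```python
from dynplex import (toy_fixture, dppm, DppmConfig, PlexParams, community_count,
                     make_scenario, cpm, CpmConfig, sensitivity_specificity)

for variant in ("edges7", "edges8", "edges9"):
    graph = toy_fixture(variant)
    shared = len(graph.layers[0] & graph.layers[1])
    n = community_count(dppm(graph, DppmConfig(PlexParams(3, 2))))
    print(f"{variant}: {shared} shared edge(s) -> {n} dynamic communities")

graph, truth = make_scenario("split", seed=1)
detected = dppm(graph, DppmConfig(PlexParams(4, 2), mode="heuristic"))
r = sensitivity_specificity(truth.true_community, detected, graph.node_count)
print(f"split scenario, DPPM (4,2): S+ = {r.sensitivity:.3f}, S- = {r.specificity:.3f}")
baseline = cpm(graph, CpmConfig(m=4, seed=1))
rc = sensitivity_specificity(truth.true_community, baseline, graph.node_count)
print(f"split scenario, CPM (m=4):  S+ = {rc.sensitivity:.3f}, S- = {rc.specificity:.3f}")
```

prints

```
edges7: 0 shared edge(s) -> 3 dynamic communities
edges8: 1 shared edge(s) -> 2 dynamic communities
edges9: 2 shared edge(s) -> 1 dynamic communities
split scenario, DPPM (4,2): S+ = 0.879, S- = 1.000
split scenario, CPM (m=4):  S+ = 0.175, S- = 1.000
```

The scenario lines score the largest detected community against a planted
64-node community that splits in two halfway through a 100-layer
simulation: sensitivity S+ = TP/(TP+FN) and specificity S− = TN/(TN+FP)
are summed over layers.  The plex walk recovers almost the whole planted
trajectory; clique percolation, which cannot tolerate missing edges,
recovers a fifth of it at the same specificity.

The same pipeline is available from the shell:

```
dynplex simulate --toy edges8 --out toy
dynplex detect --method dppm --m 3 --k 2 --input toy/network.tsv --out det
# -> 2 communities -> det/communities.tsv
```

plus `dynplex simulate --scenario split|merge|expand|contract`,
`dynplex simulate --noise`, `dynplex plexes`, `dynplex statcomm`,
`dynplex infer` (multichannel CSV → layered network TSV),
`dynplex assess`, and `dynplex stats`.  Every command writes a JSON run
manifest with the configuration and input/output hashes.

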