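# Methods

## Model and definitions

The data model is a sequence of N simple undirected graphs G_1 … G_N on a
common vertex set of p nodes (0-based node and layer indices throughout;
empty layers are legal).  A k-plex of size m is a vertex subset S with
|S| = m whose every member has at least m − k neighbors inside S; m > k ≥ 1
is required, and a 1-plex is a clique.  k-plexes are hereditary (every
subset of a k-plex is a k-plex), which both justifies the
branch-and-bound enumerator and makes "maximal" checkable by single-vertex
extension.

Static communities of one graph are the connected components of the
implicit plex-overlap graph: maximal plexes are chained when their vertex
overlap is at least m − 1 (one vertex may change per walk step).  The
overlap graph is never materialized; an inverted vertex→plex index limits
pairwise comparisons to plexes that share at least one vertex, and the
exposed object is only the component structure.  Member vertices and all
plex-internal edges carry the community label; vertices in no plex carry
none, and labels may overlap.

Dynamic communities are produced in two passes.  Pass one applies the
static step per layer.  Pass two builds, for each adjacent layer pair, an
enhanced bi-slice graph on 2p vertices containing: both layers' observed
edges, one self edge v_t—v_{t+1} per vertex, and, for each edge {u,v}
present in both layers, the mirrored railroad pair u_t—v_{t+1} and
v_t—u_{t+1}.  Maximal plexes of the bi-slice are percolated with the same
m − 1 overlap rule.  Finally, label propagation merges fragments (slice
communities and bi-slice components) to a fixed point: two fragments join
when, at some common layer, they share a labeled observed edge or at
least m − 1 labeled vertices.  Union-find computes the transitive
closure, so the result is idempotent and independent of processing
order; community ids are then canonicalized in first-appearance order by
(layer, smallest member node), making the whole pipeline deterministic.

### Cross-slice admissibility

In the over-permissive regime m − k ≤ 1 a plex may contain a vertex
attached by a single edge, so self edges alone would let plexes bridge
two slices that share no structure, collapsing clearly distinct
communities.  We therefore require any bi-slice plex that spans both
sides to contain at least one railroad edge.  Railroads exist only for
edges persisting across both layers, so cross-time movement is anchored
to shared observed structure; the deterministic ladder fixtures (0/1/2
shared edges → 3/2/1 communities) pin this behavior.  For m − k ≥ 2 the
degree arithmetic already forces railroads into any spanning plex, so
the filter only bites in the degenerate regime.  Running with the filter
disabled in that regime triggers a loud warning.

### Heuristic mode

Exact bi-slice percolation costs a maximal-plex enumeration on 2p
vertices per layer pair.  The heuristic mode skips it: per-slice
communities at t and t+1 are linked directly when their vertex overlap
exceeds m − 1 (strict by default; configurable to ≥ m − 1) and — by
default — at least one edge present in both layers is labeled in both
communities.  The edge anchor mirrors the exact rule's railroad
requirement, which is why it is the default: a heuristic link then
always implies an exact-mode merge (for m = 4, k = 2 the four copies of
a shared labeled edge form a complete, admissible bi-slice plex), so the
heuristic partition refines the exact one; the property suite asserts
this containment on random instances.  The heuristic cannot see
communities that exist only across slices (e.g. when single layers are
too sparse to hold any plex), so the exact mode is used for the noise
experiment and the ladder fixtures, and the heuristic for the long
planted-scenario recordings.

## Enumerator

The exact enumerator is a binary include/exclude backtracking over
bitset-encoded candidate and excluded sets, with three sound prunings:
a size bound (|S| + |candidates| < m), domination (an excluded vertex
adjacent to every current and future member makes all extensions
non-maximal), and, when m ≥ 2k − 1, a distance-2 candidate filter
(k-plexes of size > 2k − 2 have induced diameter ≤ 2, and are connected,
which also allows per-component search).  Correctness is checked against
an exhaustive scan of all 2^p subsets on hundreds of random graphs and
against an independent maximal-clique routine at k = 1.  Exact
enumeration refuses graphs above a configurable cap (default 512
vertices) since the worst case is exponential.  The clique-first
shortcut (maximal cliques first, plexes only among clique-free vertices)
is provided behind an explicit flag and labeled approximate: it can miss
maximal plexes that straddle cliques.

## Baseline

The CPM baseline runs clique percolation per slice (the k = 1 special
case of the static step, cross-checked against an independent
implementation) and links a community at t+1 to a predecessor at t when
they share at least `link_threshold` vertices (default 1 — the ladder
fixture outcome requires linking at overlap 1).  Maximal overlap wins;
exact ties are broken by a fair coin flip from a recorded seed, and a
repetition helper reports per-node label-inheritance frequencies, whose
tie case is validated against a binomial band.

## Synthetic data

Three generators emulate the study conditions:

* **Ladder fixtures** (deterministic, 7 nodes × 2 layers): two triangles
  plus an isolated node at t; at t+1 a single component centered on the
  previously isolated node, sharing 0, 1, or 2 edges with t.  These are
  reconstructions pinned to the textual constraints (component
  structure, edge counts, which edges are added); the original adjacency
  matrices are figure-only.
* **Noise experiment**: a connected nine-node, eight-edge template (a
  double star with centers 3 and 5 — also a reconstruction, the figure
  being unavailable) replicated for 100 layers with two uniformly chosen
  edges deleted per layer, independently across layers.  Every layer has
  six edges and consecutive layers share at least four.
* **Planted scenarios** (64 nodes; 100 layers for split/merge, 140 for
  expand/contract; one layer per second): a multilayer label matrix
  assigns the planted label to active blocks (15-node communities, plus
  10-node increments for expand) on a fixed schedule of 20-second
  intervals; all other node-layer cells draw independent uniform labels
  in 1..64, producing the transient coincidental groups that act as
  background clutter.  Contract is expand with the time axis reversed.
  Layer edges come from a degree-corrected (Chung–Lu-style) sampler
  within same-label groups only (zero mixing): expected degrees are
  drawn from a truncated discrete power law with exponent −2 on degrees
  3..20, capped at group size − 1; a block that leaves a node isolated
  is resampled up to 100 times, after which the best attempt is kept and
  the rejection logged.  Only these printed parameters of the original
  multilayer benchmark generator are reproduced; its interlayer
  dependence beyond the label matrix is not, since the detection methods
  consume edges, not sampler internals.

What passing on these generators does *not* show: the scenario sampler
has no between-block edges and no temporal edge correlation within an
active block, so real recordings — where noise is structured and
communities are not sampled independently per second — are harder than
this benchmark in ways the tests do not probe.

## Functional-network inference

The front-end turns a channels × samples voltage array into one binary
graph per window: zero-phase forward-reverse FIR band-pass (order 1000,
4–50 Hz defaults), 1 s windows with 0.5 s overlap (tail remainders
dropped), per-channel normalization to zero mean and unit variance
(flat channels flagged and excluded from edges).  The pair statistic is
the maximum absolute cross-correlation over lags up to ±0.2 s.  Its null
scale σ² is a single dataset-wide number: the average, over all pairs
and windows, of the variance of the cross-correlation sequence across
scanned lags.  The statistic maps to a p-value as the maximum of the
2L+1 per-lag two-sided normal tests treated as independent
(p = 1 − (2Φ(s/σ) − 1)^(2L+1)); for band-limited data neighboring lags
are positively correlated, so this is conservative, which is the right
side to err on for edge inclusion.  Benjamini–Hochberg FDR at q = 0.05
is applied within each window.  Every knob (band, order, window,
overlap, lag range, q) is a config field recorded in run manifests; the
pipeline has no randomness.

## Assessment

Sensitivity S+ = TP/(TP+FN) and specificity S− = TN/(TN+FP) compare the
largest detected community c_L(t) (greatest total node-layer extent;
ties broken by first layer, then smallest member node) with the planted
trajectory c_T(t), cells summed over layers; the four cells always total
p·N, and S+ is flagged undefined when the truth is empty everywhere.
Community lifespan is (last − first + 1) layers × a layer-seconds
factor (default 1 s for simulations, 0.5 s for inferred networks whose
layers hop by half a window); the first-to-last convention counts
interior layers where the community is absent, a deliberate choice noted
here because gap handling is not otherwise pinned.  Node loyalty is the
fraction of layers a node carries any (or one specific) label.
Recruitment order ranks nodes by first joining layer with mid-rank ties;
a median-across-runs reducer propagates never-joined nodes as missing.

## Problem sizes and numerical choices

The replication counts used by the shipped experiments are the package's
own balance of statistical resolution against desk-scale runtime: 100
seeds for the noise experiment, 8 seeds per scenario in the acceptance
script (3 in the test suite), 200 random graphs for enumerator/oracle
agreement, and 100 s of 64-channel synthetic data for the inference
checks.  All randomness flows through explicit integer seeds;
per-stage seeds are split deterministically from one global seed.
Community detection itself contains no randomness except the CPM
tie-break, whose seed is part of its configuration.

## Known limitations

* Exact bi-slice enumeration is exponential in the worst case; for long
  dense recordings the heuristic mode is the practical path, and it can
  miss cross-slice-only communities and the documented m-cycle/isomorph
  equivalences.
* Weighted and directed networks, links across non-adjacent layers, and
  time-varying plex order are out of scope.
* On the noise benchmark the plex walk occasionally reports short-lived
  two-node satellite communities (an isolated persistent edge) alongside
  the dominant tube, and the tube itself can split into parallel chains;
  the m − 1 overlap threshold cannot absorb either, so "exactly one
  community" holds only for a minority of noise realizations even though
  the dominant community always starts at the first layer and reaches
  every template node.
* The multilayer-modularity comparison method is external published code
  and is not implemented; its parameter grids (γ ∈ {0.01, 0.1, 0.5, 1, 2},
  ω ∈ {0.01, 0.1, 0.5, 1, 2, 5, 10}, Newman–Girvan null, and a
  post-filter dropping communities smaller than 3 nodes or lasting one
  step) are recorded here for completeness only.
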