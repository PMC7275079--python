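"""Bi-slice construction, admissibility, and DPPM driver semantics."""

import random

import pytest

from dynplex import (
    CommunityAssignment,
    DppmConfig,
    LayeredGraph,
    PlexParams,
    admissible_bislice_plexes,
    build_bislice,
    community_count,
    dppm,
    propagate_labels,
    toy_fixture,
)
from dynplex.dynamic_comm import Fragment

from conftest import random_edges

K4 = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def _extent_sets(assignment):
    """Each community as a frozenset of (layer, node) elements."""
    by_id = {}
    for (t, v), ids in assignment.vertex_labels.items():
        for cid in ids:
            by_id.setdefault(cid, set()).add((t, v))
    return {frozenset(s) for s in by_id.values()}


class TestBislice:
    def test_persistent_path_edge_counts(self):
        path = [(0, 1), (1, 2)]
        b = build_bislice(3, path, path)
        assert len(b.observed_t) == 2 and len(b.observed_t1) == 2
        assert len(b.self_edges()) == 3
        assert len(b.railroad_edges()) == 4  # 2 persistent edges, mirrored
        assert len(b.all_edges()) == 4 + 3 + 4

    def test_disjoint_layers_have_no_railroads(self):
        b = build_bislice(4, [(0, 1)], [(2, 3)])
        assert b.railroad_edges() == []
        assert len(b.self_edges()) == 4

    def test_persistent_triangle_edge_spans_complete_quad(self):
        tri = [(0, 1), (0, 2), (1, 2)]
        b = build_bislice(3, tri, tri)
        quad = {0, 1, 3, 4}  # copies of the persistent edge {0,1}
        present = {frozenset(e) for e in b.all_edges()}
        for a in quad:
            for c in quad:
                if a < c:
                    assert frozenset({a, c}) in present

    def test_mismatched_node_count_rejected(self):
        with pytest.raises(ValueError):
            LayeredGraph.from_edge_lists(2, [[(0, 1)], [(1, 2)]])


class TestAdmissibility:
    def test_persistent_edge_quad_admissible(self):
        b = build_bislice(2, [(0, 1)], [(0, 1)])
        out = admissible_bislice_plexes(b, PlexParams(4, 2))
        assert {p.members for p in out} == {frozenset({0, 1, 2, 3})}

    def test_self_edge_only_bridge_filtered(self):
        # edge {0,1} exists only at t; {0_t, 1_t, 0_{t+1}} is a 2-plex by
        # degrees but crosses time without any railroad
        b = build_bislice(2, [(0, 1)], [])
        out = admissible_bislice_plexes(b, PlexParams(3, 2))
        assert all(min(p.members) >= 2 or max(p.members) < 2 for p in out)
        unfiltered = admissible_bislice_plexes(
            b, PlexParams(3, 2), cross_slice_admissibility=False
        )
        assert any(
            min(p.members) < 2 <= max(p.members) for p in unfiltered
        )

    def test_incident_persistent_edges_bridge(self):
        edges = [(0, 1), (1, 2)]
        b = build_bislice(3, edges, edges)
        out = {p.members for p in admissible_bislice_plexes(b, PlexParams(4, 2))}
        assert frozenset({0, 1, 2, 4}) in out  # {u_t, v_t, w_t, v_{t+1}}


class TestDppmToyLadder:
    @pytest.mark.parametrize(
        "variant,expected", [("edges7", 3), ("edges8", 2), ("edges9", 1)]
    )
    def test_shared_edges_control_community_count(self, variant, expected):
        assignment = dppm(toy_fixture(variant), DppmConfig(PlexParams(3, 2)))
        assert community_count(assignment) == expected

    def test_constant_k4_single_community_covering_everything(self):
        g = LayeredGraph.from_edge_lists(4, [K4] * 5)
        a = dppm(g, DppmConfig(PlexParams(4, 2)))
        assert community_count(a) == 1
        assert set(a.vertex_labels) == {(t, v) for t in range(5) for v in range(4)}

    def test_time_reversal_symmetry(self):
        for variant in ("edges7", "edges8", "edges9"):
            g = toy_fixture(variant)
            fwd = dppm(g, DppmConfig(PlexParams(3, 2)))
            rev = dppm(g.reversed_time(), DppmConfig(PlexParams(3, 2)))
            n = g.layer_count
            mirrored = {
                frozenset((n - 1 - t, v) for t, v in s) for s in _extent_sets(rev)
            }
            assert mirrored == _extent_sets(fwd)

    def test_determinism(self):
        g = toy_fixture("edges8")
        a = dppm(g, DppmConfig(PlexParams(3, 2)))
        b = dppm(g, DppmConfig(PlexParams(3, 2)))
        assert a.vertex_labels == b.vertex_labels and a.edge_labels == b.edge_labels

    def test_degenerate_regime_without_admissibility_warns(self):
        g = toy_fixture("edges7")
        with pytest.warns(UserWarning, match="over-merge"):
            dppm(g, DppmConfig(PlexParams(3, 2), cross_slice_admissibility=False))


class TestPropagateLabels:
    def test_chain_of_fragments_sharing_edges_gets_single_id(self):
        frags = []
        for t in range(4):
            f = Fragment()
            for v in (0, 1, 2, 3):
                f.add_vertex(t, v)
                f.add_vertex(t + 1, v)
            f.add_edge(t, (0, 1))
            f.add_edge(t + 1, (0, 1))
            frags.append(f)
        out = propagate_labels(frags, PlexParams(4, 2))
        assert len(out.community_ids()) == 1

    def test_single_shared_vertex_does_not_merge(self):
        f1 = Fragment()
        f2 = Fragment()
        for v in (0, 1, 2, 3):
            f1.add_vertex(0, v)
        for v in (3, 4, 5, 6):
            f2.add_vertex(0, v)
        out = propagate_labels([f1, f2], PlexParams(4, 2))
        assert len(out.community_ids()) == 2

    def test_m_minus_1_shared_vertices_merge(self):
        f1 = Fragment()
        f2 = Fragment()
        for v in (0, 1, 2, 3):
            f1.add_vertex(0, v)
        for v in (1, 2, 3, 6):
            f2.add_vertex(0, v)
        out = propagate_labels([f1, f2], PlexParams(4, 2))
        assert len(out.community_ids()) == 1

    def test_no_fragments_gives_empty_assignment(self):
        out = propagate_labels([], PlexParams(4, 2))
        assert out.vertex_labels == {} and out.edge_labels == {}

    def test_order_independence(self, rng):
        frags = []
        for i in range(6):
            f = Fragment()
            for v in range(i, i + 4):
                f.add_vertex(0, v)
            frags.append(f)
        base = _extent_sets(propagate_labels(frags, PlexParams(4, 2)))
        shuffled = frags[:]
        rng.shuffle(shuffled)
        assert _extent_sets(propagate_labels(shuffled, PlexParams(4, 2))) == base


class TestHeuristicVsExact:
    def test_heuristic_links_imply_exact_links(self):
        """Every heuristic merge of slice communities must also occur in
        exact mode: edge-anchored overlap linking is a lower bound on the
        bi-slice plex walk."""
        rng = random.Random(7)
        checked = 0
        for _ in range(12):
            p = rng.randint(6, 10)
            n_layers = rng.randint(2, 4)
            layers = [random_edges(rng, p, 0.45) for _ in range(n_layers)]
            g = LayeredGraph.from_edge_lists(p, layers)
            params = PlexParams(4, 2)
            exact = dppm(g, DppmConfig(params, mode="exact"))
            heur = dppm(g, DppmConfig(params, mode="heuristic"))
            # map: every heuristic community's element set must be contained
            # in a single exact community's element set
            exact_sets = _extent_sets(exact)
            for hset in _extent_sets(heur):
                assert any(hset <= eset for eset in exact_sets), (
                    p, layers, sorted(hset))
                checked += 1
        assert checked > 0
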