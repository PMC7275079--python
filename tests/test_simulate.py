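"""Benchmark generators: schedules, degree model, noise sim, toy fixtures."""

import numpy as np
import pytest

from dynplex import (
    DegreeModelParams,
    make_scenario,
    noise_template_sim,
    sample_layer,
    scenario_labels,
    toy_fixture,
)
from dynplex.simulate import NOISE_TEMPLATE, PLANTED_LABEL


def _interval_truth_sizes(truth, interval_len=20):
    sizes = []
    for start in range(0, truth.layer_count, interval_len):
        block = {len(truth.true_community[t]) for t in range(start, start + interval_len)}
        assert len(block) == 1  # constant within an interval
        sizes.append(block.pop())
    return tuple(sizes)


class TestScenarioSchedules:
    def test_split_interval_sizes(self):
        truth = scenario_labels("split", seed=3)
        assert truth.layer_count == 100
        assert _interval_truth_sizes(truth) == (0, 15, 45, 30, 0)

    def test_merge_interval_sizes(self):
        truth = scenario_labels("merge", seed=3)
        assert _interval_truth_sizes(truth) == (0, 30, 45, 15, 0)

    def test_expand_interval_sizes(self):
        truth = scenario_labels("expand", seed=3)
        assert truth.layer_count == 140
        assert _interval_truth_sizes(truth) == (0, 15, 25, 35, 45, 55, 0)

    def test_contract_is_time_reversed_expand(self):
        c = scenario_labels("contract", seed=9)
        e = scenario_labels("expand", seed=9)
        for t in range(140):
            assert c.true_community[t] == e.true_community[139 - t]
        assert np.array_equal(c.label_matrix, e.label_matrix[:, ::-1])

    def test_random_labels_in_range(self):
        truth = scenario_labels("split", seed=0)
        inactive = truth.label_matrix[:, 0]  # first interval: all random
        assert inactive.min() >= 1 and inactive.max() <= 64

    def test_truth_deterministic_given_seed(self):
        a = scenario_labels("merge", seed=4)
        b = scenario_labels("merge", seed=4)
        assert np.array_equal(a.label_matrix, b.label_matrix)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_labels("explode", seed=0)


class TestDegreeModel:
    def test_all_distinct_labels_give_empty_layer(self):
        labels = np.arange(64)
        rng = np.random.default_rng(0)
        assert sample_layer(labels, DegreeModelParams(), rng) == set()

    def test_zero_mixing_never_crosses_blocks(self):
        labels = np.array([0] * 15 + [1] * 15 + [2] * 34)
        rng = np.random.default_rng(1)
        for _ in range(20):
            for u, v in sample_layer(labels, DegreeModelParams(), rng):
                assert labels[u] == labels[v]

    def test_single_block_degrees_near_powerlaw_targets(self):
        """Monte-Carlo: realized mean degree of one 64-node block tracks the
        truncated power-law target mean."""
        params = DegreeModelParams()
        support = np.arange(params.min_degree, params.max_degree + 1, dtype=float)
        probs = support ** params.powerlaw_exponent
        target_mean = (support * probs / probs.sum()).sum()
        labels = np.zeros(64, dtype=int)
        rng = np.random.default_rng(42)
        degs = []
        for _ in range(60):
            edges = sample_layer(labels, params, rng)
            deg = np.zeros(64)
            for u, v in edges:
                deg[u] += 1
                deg[v] += 1
            degs.append(deg.mean())
        realized = np.mean(degs)
        assert 0.7 * target_mean <= realized <= 1.15 * target_mean

    def test_nonzero_mixing_not_modeled(self):
        with pytest.raises(NotImplementedError):
            sample_layer(np.zeros(4, dtype=int),
                         DegreeModelParams(mixing=0.1), np.random.default_rng(0))


class TestMakeScenario:
    def test_deterministic_and_planted_edges_only_within_block(self):
        g1, t1 = make_scenario("split", seed=5)
        g2, _ = make_scenario("split", seed=5)
        assert g1 == g2
        for t in range(20, 40):  # interval 2: only c2 = nodes 15..29 planted
            planted = t1.true_community[t]
            for u, v in g1.layers[t]:
                lu, lv = t1.label_matrix[u, t], t1.label_matrix[v, t]
                assert lu == lv
                if u in planted or v in planted:
                    assert lu == PLANTED_LABEL and u in planted and v in planted

    def test_contract_layers_reverse_expand(self):
        ge, _ = make_scenario("expand", seed=2)
        gc, _ = make_scenario("contract", seed=2)
        assert gc.layers == tuple(reversed(ge.layers))


class TestNoiseSim:
    def test_layer_size_and_subgraph_property(self):
        g = noise_template_sim(seed=3)
        template = set(NOISE_TEMPLATE)
        assert g.layer_count == 100 and g.node_count == 9
        for layer in g.layers:
            assert len(layer) == 6
            assert set(layer) <= template

    def test_consecutive_layers_share_at_least_four_edges(self):
        g = noise_template_sim(seed=8)
        for t in range(g.layer_count - 1):
            assert len(g.layers[t] & g.layers[t + 1]) >= 4

    def test_template_validation(self):
        with pytest.raises(ValueError):
            noise_template_sim(template=[(0, 1), (1, 2)])
        g = noise_template_sim(template=[(0, 1), (1, 2), (2, 3)],
                               steps=5, removals=1, force=True)
        assert g.layer_count == 5
        assert all(len(layer) == 2 for layer in g.layers)

    def test_deterministic_given_seed(self):
        assert noise_template_sim(seed=4) == noise_template_sim(seed=4)


class TestToyFixture:
    def test_edge_counts_and_shared_edges(self):
        for variant, n_edges, shared in [("edges7", 7, 0), ("edges8", 8, 1),
                                         ("edges9", 9, 2)]:
            g = toy_fixture(variant)
            assert g.node_count == 7 and g.layer_count == 2
            assert len(g.layers[0]) == 6
            assert len(g.layers[1]) == n_edges
            assert len(g.layers[0] & g.layers[1]) == shared

    def test_layer0_is_two_triangles_with_isolated_node(self):
        g = toy_fixture("edges7")
        assert g.layers[0] == frozenset(
            {(0, 1), (0, 2), (1, 2), (4, 5), (4, 6), (5, 6)})

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            toy_fixture("edges10")
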