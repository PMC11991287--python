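import itertools

import numpy as np
import pytest
from scipy import integrate

from grwnet.network import WeightedNetwork
from grwnet.weakties import (
    Partition,
    alpha_closed_form,
    confidence_filter,
    detect_modules,
    edge_confidence,
    global_weight_filter,
    intermodular_density,
    intra_inter_mean_weights,
    modularity,
    weak_ties_spectrum,
)


def two_cliques(size: int = 10) -> WeightedNetwork:
    edges = [(i, j) for i, j in itertools.combinations(range(size), 2)]
    edges += [(i + size, j + size) for i, j in itertools.combinations(range(size), 2)]
    edges += [(size - 1, size)]
    e = np.array(edges)
    return WeightedNetwork(2 * size, e, np.ones(len(e)))


class TestDetectModules:
    def test_two_cliques_split_matches_bipartition_oracle(self):
        """Louvain recovers the modularity-optimal bipartition of two joined cliques."""
        net = two_cliques(10)
        part = detect_modules(net, seed=0)
        labels = part.labels
        assert part.n_modules == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        # oracle: exhaustive search over all bipartitions of the 6-node version
        small = two_cliques(3)
        best_q, best_split = -1.0, None
        for bits in range(1, 2**6 - 1):
            lab = np.array([(bits >> i) & 1 for i in range(6)])
            q = modularity(small, Partition(lab))
            if q > best_q:
                best_q, best_split = q, lab
        found = detect_modules(small, seed=1)
        assert modularity(small, found) == pytest.approx(best_q)
        assert (best_split[:3] == best_split[0]).all() and (best_split[3:] == best_split[3]).all()

    def test_complete_graph_single_module(self):
        e = np.array(list(itertools.combinations(range(8), 2)))
        net = WeightedNetwork(8, e, np.ones(len(e)))
        assert detect_modules(net, seed=0).n_modules == 1

    def test_deterministic_given_seed(self, medium_ws1):
        net, _, _ = medium_ws1
        p1 = detect_modules(net, seed=99)
        p2 = detect_modules(net, seed=99)
        assert np.array_equal(p1.labels, p2.labels)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(WeightedNetwork(3, np.zeros((0, 2), int), np.zeros(0)))


class TestGlobalWeightFilter:
    def test_full_percentage_is_identity(self, toy_network):
        out = global_weight_filter(toy_network, 100)
        assert np.array_equal(out.edges, toy_network.edges)

    def test_keeps_lowest_weights(self):
        net = WeightedNetwork(5, np.array([[0, 1], [1, 2], [2, 3], [3, 4]]),
                              np.array([1.0, 2.0, 3.0, 4.0]))
        out = global_weight_filter(net, 50)
        assert sorted(out.weights.tolist()) == [1.0, 2.0]

    def test_tied_weights_stable_count(self):
        net = WeightedNetwork(6, np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5]]),
                              np.ones(5))
        out = global_weight_filter(net, 40)
        assert out.n_edges == 2  # ceil(0.4·5); ties broken by edge index
        # first two canonical edges survive
        assert out.edges.tolist() == [[0, 1], [1, 2]]

    def test_nested_across_percentages(self, medium_ws1):
        net, _, _ = medium_ws1
        sets = []
        for p in (5, 20, 60, 100):
            sub = global_weight_filter(net, p)
            sets.append({tuple(e) for e in sub.edges.tolist()})
        for a, b in zip(sets, sets[1:]):
            assert a <= b

    def test_out_of_range_rejected(self, toy_network):
        for p in (0, -1, 101):
            with pytest.raises(ValueError):
                global_weight_filter(toy_network, p)


class TestAlpha:
    def test_zero_weight_never_significant(self):
        assert alpha_closed_form(0.0, 5) == pytest.approx(1.0)

    def test_k2_half(self):
        assert alpha_closed_form(0.5, 2) == pytest.approx(0.5)

    def test_full_weight_always_significant(self):
        assert alpha_closed_form(1.0, 4) == pytest.approx(0.0)

    def test_degree_one_convention(self):
        assert alpha_closed_form(1.0, 1) == pytest.approx(1.0)

    def test_closed_form_equals_quadrature(self):
        """α = (1−w/s)^{k−1} agrees with the defining integral to 1e-10."""
        for k in (2, 3, 7, 25, 100):
            for ws in (0.01, 0.2, 0.5, 0.8, 0.99):
                integral, _ = integrate.quad(lambda x: (1 - x) ** (k - 2), 0, ws)
                assert alpha_closed_form(ws, k) == pytest.approx(
                    1 - (k - 1) * integral, abs=1e-10
                )

    def test_weight_above_strength_rejected(self):
        with pytest.raises(ValueError, match="corrupt"):
            alpha_closed_form(1.5, 3)

    def test_edge_confidence_two_endpoints(self, toy_network):
        out = edge_confidence(toy_network)
        assert np.all(out["alpha"] <= out["alpha_i"] + 1e-15)
        assert np.all(out["alpha"] <= out["alpha_j"] + 1e-15)
        np.testing.assert_allclose(out["confidence"], 1 - out["alpha"])


class TestConfidenceFilter:
    def test_full_percentage_is_identity(self, toy_network):
        out = confidence_filter(toy_network, 100)
        assert np.array_equal(out.edges, toy_network.edges)

    def test_star_graph_filters_coincide(self):
        """On a star, confidence grows with weight, so both filters select
        the same edge sets at every percentage."""
        k = 9
        edges = np.array([[0, i] for i in range(1, k + 1)])
        net = WeightedNetwork(k + 1, edges, np.linspace(1.0, 5.0, k))
        for p in (20, 40, 60, 80, 100):
            a = {tuple(e) for e in global_weight_filter(net, p).edges.tolist()}
            b = {tuple(e) for e in confidence_filter(net, p).edges.tolist()}
            assert a == b

    def test_nested(self, medium_ws1):
        net, _, _ = medium_ws1
        prev = set()
        for p in (2, 10, 50, 100):
            cur = {tuple(e) for e in confidence_filter(net, p).edges.tolist()}
            assert prev <= cur
            prev = cur


class TestIntermodularDensity:
    def test_single_module_zero(self, toy_network):
        assert intermodular_density(toy_network, Partition(np.zeros(5))) == 0.0

    def test_singleton_modules_one(self, toy_network):
        assert intermodular_density(toy_network, Partition(np.arange(5))) == 1.0

    def test_two_triangles_one_seventh(self, two_triangles):
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        assert intermodular_density(two_triangles, part) == pytest.approx(1 / 7)


class TestSpectrum:
    def test_normalization_point(self, two_triangles):
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        spec = weak_ties_spectrum(two_triangles, part, "weight",
                                  np.array([50.0, 100.0]))
        assert spec.rho_inter[-1] == pytest.approx(1.0)

    def test_single_module_flagged_undefined(self, toy_network):
        spec = weak_ties_spectrum(toy_network, Partition(np.zeros(5)), "weight",
                                  np.array([50.0, 100.0]))
        assert spec.undefined and np.all(np.isnan(spec.rho_inter))

    def test_percents_must_include_100(self, toy_network):
        with pytest.raises(ValueError):
            weak_ties_spectrum(toy_network, Partition(np.arange(5)), "weight",
                               np.array([10.0, 50.0]))


class TestIntraInter:
    def test_hand_example(self):
        # module A: edges 1 and 3 (mean 2); module B: edges 3 and 5 (mean 4);
        # one inter edge of weight 1 → (3, 1)
        edges = np.array([[0, 1], [1, 2], [3, 4], [4, 5], [2, 3]])
        w = np.array([1.0, 3.0, 3.0, 5.0, 1.0])
        net = WeightedNetwork(6, edges, w)
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        intra, inter = intra_inter_mean_weights(net, part)
        assert (intra, inter) == (pytest.approx(3.0), pytest.approx(1.0))

    def test_single_module_rejected(self, toy_network):
        with pytest.raises(ValueError):
            intra_inter_mean_weights(toy_network, Partition(np.zeros(5)))
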