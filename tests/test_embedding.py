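import itertools

import numpy as np
import pytest

from grwnet.embedding import (
    fit_sigma_relation,
    infer_angles,
    infer_beta,
    infer_hidden_degrees,
    log_likelihood,
)
from grwnet.model import ModelParams, connection_probability, generate_network, kappa_law_mean
from grwnet.network import WeightedNetwork


class TestLogLikelihood:
    def test_two_nodes_chi_one_edge(self):
        # geometry arranged so p = 1/2 exactly
        n = 2
        radius = n / (2 * np.pi)
        mu = radius * 1.0 / 4.0  # Δθ = 1, κκ' = 4 → χ = 1
        a = np.array([[0, 1], [1, 0]])
        ll = log_likelihood(a, np.array([0.0, 1.0]), np.array([2.0, 2.0]), 2.0, mu)
        assert ll == pytest.approx(np.log(0.5))

    def test_three_node_brute_force_oracle(self):
        n = 3
        thetas = np.array([0.3, 2.0, 4.4])
        kappas = np.array([1.5, 3.0, 0.8])
        beta, mu = 2.2, 0.21
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        p = ModelParams(n_nodes=n, beta=beta, mu=mu)
        direct = 0.0
        for i, j in itertools.combinations(range(n), 2):
            pij = float(connection_probability(thetas[i], thetas[j], kappas[i], kappas[j], p))
            direct += np.log(pij) if a[i, j] else np.log(1 - pij)
        assert log_likelihood(a, thetas, kappas, beta, mu) == pytest.approx(direct, abs=1e-12)

    def test_impossible_edge_gives_neg_inf(self):
        # coincident nodes: p = 1 exactly, but the pair is NOT linked
        a = np.array([[0, 0], [0, 0]])
        ll = log_likelihood(a, np.array([1.0, 1.0]), np.array([2.0, 2.0]), 2.0, 0.1)
        assert ll == -np.inf

    def test_nonpositive_upper_bound(self):
        rng = np.random.default_rng(0)
        a = (rng.random((6, 6)) < 0.4).astype(int)
        a = np.triu(a, 1) + np.triu(a, 1).T
        ll = log_likelihood(a, rng.random(6) * 2 * np.pi, rng.random(6) + 0.5, 2.5, 0.1)
        assert ll <= 0


class TestHiddenDegrees:
    def test_regular_degrees_give_equal_kappa(self):
        kappa = infer_hidden_degrees(np.full(50, 6.0), beta=2.5, mu=0.05)
        assert np.allclose(kappa, kappa[0])

    def test_expected_degree_matches_observed_within_tolerance(self, medium_ws1):
        net, _, params = medium_ws1
        k = net.degrees().astype(float)
        k = k[k > 0]
        kappa = infer_hidden_degrees(k, params.beta, params.mu, tol=0.01)
        from grwnet.embedding import _expected_degrees

        ek = _expected_degrees(kappa, params.beta, params.mu, len(k) / (2 * np.pi))
        assert np.max(np.abs(ek - k) / k) < 0.01

    def test_kappa_monotone_in_degree(self):
        k_obs = np.array([2.0, 5.0, 9.0, 20.0, 41.0] + [4.0] * 80)
        kappa = infer_hidden_degrees(k_obs, beta=2.5, mu=0.05)
        order = np.argsort(k_obs[:5])
        assert np.all(np.diff(kappa[:5][order]) > 0)

    def test_zero_degree_rejected(self):
        with pytest.raises(ValueError):
            infer_hidden_degrees(np.array([0.0, 3.0]), 2.5, 0.1)


class TestInferBeta:
    def test_above_one_and_monotone_with_clustering(self):
        """Networks generated at higher β must yield higher β̂."""
        bhats = []
        for beta_true in (1.8, 6.0):
            p = ModelParams(n_nodes=600, seed=31, beta=beta_true)
            net, _, _ = generate_network(
                p, target_mean_degree=kappa_law_mean(p.kappa_law, 600)
            )
            bhat, _, _ = infer_beta(net, n_ensemble=2, seed=0)
            bhats.append(bhat)
            assert bhat > 1.0
        assert bhats[1] > bhats[0]


class TestInferAngles:
    def test_deterministic_given_seed(self):
        p = ModelParams(n_nodes=120, seed=8, beta=3.0)
        net, nodes, fitted = generate_network(p, target_mean_degree=8.0)
        k = net.degrees()
        live = np.flatnonzero(k > 0)
        a = net.adjacency()[np.ix_(live, live)]
        t1 = infer_angles(a, nodes.kappa[live], fitted.beta, fitted.mu, seed=4)
        t2 = infer_angles(a, nodes.kappa[live], fitted.beta, fitted.mu, seed=4)
        assert np.array_equal(t1, t2)

    def test_improves_over_spectral_initialization(self):
        """Likelihood ascent: the refined angles cannot be worse than the
        network under a random angle assignment, and the reported likelihood
        is finite."""
        p = ModelParams(n_nodes=150, seed=9, beta=2.5)
        net, nodes, fitted = generate_network(p, target_mean_degree=10.0)
        k = net.degrees()
        live = np.flatnonzero(k > 0)
        a = net.adjacency()[np.ix_(live, live)]
        kap = nodes.kappa[live]
        theta_hat = infer_angles(a, kap, fitted.beta, fitted.mu, seed=0)
        rng = np.random.default_rng(1)
        ll_hat = log_likelihood(a, theta_hat, kap, fitted.beta, fitted.mu)
        ll_rand = log_likelihood(a, rng.random(len(kap)) * 2 * np.pi, kap,
                                 fitted.beta, fitted.mu)
        assert np.isfinite(ll_hat) and ll_hat > ll_rand


class TestReplicaValidation:
    def test_replica_ensemble_matches_data_moments(self):
        """Full loop (embed → regenerate): replica mean degree, strength and
        weight reproduce the data's within 10%."""
        p = ModelParams(n_nodes=400, seed=27, tau=0.4, eta=0.9, beta=2.5)
        net, _, _ = generate_network(
            p, target_mean_degree=kappa_law_mean(p.kappa_law, 400)
        )
        assert (net.degrees() > 0).all()
        from grwnet.embedding import replica_validation

        out = replica_validation(net, seed=0, n_replicas=30)
        for name in ("weights", "strengths", "degrees"):
            assert out[name]["moment_ratio"] == pytest.approx(1.0, abs=0.1), name
            assert 0.0 <= out[name]["inside_band_fraction"] <= 1.0


class TestSigmaRelation:
    def test_exact_linear_relation(self):
        # s = 2k exactly: star-free graph with unit structure
        rng = np.random.default_rng(2)
        n = 60
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < 0.2
        net = WeightedNetwork(n, np.column_stack([iu[keep], ju[keep]]),
                              np.full(int(keep.sum()), 2.0))
        a, eta = fit_sigma_relation(net)
        assert eta == pytest.approx(1.0, abs=1e-9)
        assert a == pytest.approx(2.0, rel=1e-9)

    def test_recovers_generative_eta(self):
        p = ModelParams(n_nodes=1500, seed=17, tau=0.5, eta=0.9)
        net, _, _ = generate_network(
            p, target_mean_degree=kappa_law_mean(p.kappa_law, 1500)
        )
        _, eta = fit_sigma_relation(net)
        assert eta == pytest.approx(0.9, abs=0.1)
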