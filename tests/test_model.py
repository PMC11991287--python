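import numpy as np
import pytest
from scipy import stats as sps

from grwnet.model import (
    CalibrationError,
    ModelParams,
    ParameterError,
    assign_weights,
    calibrate_mu,
    calibrate_nu,
    connection_probability,
    expected_mean_degree,
    generate_cohort,
    generate_network,
    generate_topology,
    kappa_law_mean,
    sample_nodes,
    truncated_powerlaw_mean,
)
from grwnet.network import NodeTable

from conftest import ring_nodes


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(beta=1.0), dict(tau=1.0), dict(tau=-0.1), dict(mu=0.0), dict(n_nodes=0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParams(n_nodes=kwargs.pop("n_nodes", 10), **kwargs)


class TestSampleNodes:
    def test_sigma_equals_kappa_when_a_eta_one(self):
        p = ModelParams(
            n_nodes=2, a=1.0, eta=1.0, kappa_law={"type": "list", "values": [2.0, 3.0]}
        )
        nodes = sample_nodes(p)
        assert nodes.sigma.tolist() == [2.0, 3.0]

    def test_deterministic_given_seed(self):
        p = ModelParams(n_nodes=1000, seed=42)
        a, b = sample_nodes(p), sample_nodes(p)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.kappa, b.kappa)

    def test_powerlaw_mean_matches_analytic(self):
        law = {"type": "powerlaw", "gamma": 2.7, "kappa_min": 2.0, "kappa_max": 100.0}
        p = ModelParams(n_nodes=5000, seed=3, kappa_law=law)
        kappa = sample_nodes(p).kappa
        analytic = truncated_powerlaw_mean(2.7, 2.0, 100.0)
        se = kappa.std(ddof=1) / np.sqrt(len(kappa))
        assert abs(kappa.mean() - analytic) < 3 * se

    def test_invalid_law_rejected(self):
        with pytest.raises(ParameterError):
            sample_nodes(ModelParams(n_nodes=5, kappa_law={"type": "nope"}))


class TestConnectionProbability:
    def test_half_at_unit_chi(self):
        # place two nodes so that d = μ κ_i κ_j exactly
        p = ModelParams(n_nodes=10, beta=3.0, mu=0.1)
        d_target = p.mu * 2.0 * 3.0
        dtheta = d_target / p.radius
        assert connection_probability(0.0, dtheta, 2.0, 3.0, p) == pytest.approx(0.5)

    def test_direct_evaluation_chi2_beta2(self):
        p = ModelParams(n_nodes=10, beta=2.0, mu=0.1)
        dtheta = 2.0 * p.mu * 4.0 / p.radius  # χ = 2 with κκ' = 4
        assert connection_probability(0.0, dtheta, 2.0, 2.0, p) == pytest.approx(0.2)

    def test_zero_distance_gives_certain_edge(self):
        p = ModelParams(n_nodes=10)
        assert connection_probability(1.0, 1.0, 2.0, 2.0, p) == pytest.approx(1.0)

    def test_monotone_in_distance_and_kappa(self):
        p = ModelParams(n_nodes=100, beta=2.5, mu=0.05)
        dth = np.linspace(0.01, np.pi, 50)
        probs = connection_probability(np.zeros(50), dth, 5.0, 5.0, p)
        assert np.all(np.diff(probs) < 0)
        kk = np.linspace(1, 50, 50)
        probs_k = connection_probability(0.0, 1.0, kk, 5.0, p)
        assert np.all(np.diff(probs_k) > 0)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ParameterError):
            connection_probability(0.0, 1.0, 0.0, 1.0, ModelParams(n_nodes=5))


class TestCalibrateMu:
    def test_deterministic(self):
        p = ModelParams(n_nodes=500, seed=9)
        assert calibrate_mu(p, 10.0) == calibrate_mu(p, 10.0)

    def test_mu_roughly_linear_in_target(self):
        p = ModelParams(n_nodes=500, seed=9)
        mu1 = calibrate_mu(p, 5.0)
        mu2 = calibrate_mu(p, 10.0)
        assert mu2 / mu1 == pytest.approx(2.0, rel=0.25)

    def test_monte_carlo_mean_degree_const_kappa(self):
        # β=2.5, κ≡10, n=2000, target <k>=20: ensemble mean within [19, 21]
        p = ModelParams(
            n_nodes=2000, beta=2.5, seed=1, kappa_law={"type": "constant", "value": 10.0}
        )
        nodes = sample_nodes(p)
        mu = calibrate_mu(p, 20.0, nodes)
        from dataclasses import replace

        pm = replace(p, mu=mu)
        rng = np.random.default_rng(7)
        means = [generate_topology(nodes, pm, rng).degrees().mean() for _ in range(20)]
        assert 19.0 < np.mean(means) < 21.0

    def test_infeasible_target_rejected(self):
        with pytest.raises(ParameterError):
            calibrate_mu(ModelParams(n_nodes=10), 20.0)


class TestGenerateTopology:
    def test_high_beta_chi_below_one_is_near_certain(self):
        # two nodes with χ < 1 and β = 50: edge in ≥ 99% of realizations
        p = ModelParams(n_nodes=2, beta=50.0, mu=1.0, kappa_law={"type": "constant", "value": 2.0})
        nodes = NodeTable(theta=[0.0, 1.0], kappa=[2.0, 2.0], sigma=[2.0, 2.0])
        # χ = d/(μκκ') = (2/(2π))·1/4 ≈ 0.08 < 1
        rng = np.random.default_rng(0)
        hits = sum(generate_topology(nodes, p, rng).n_edges for _ in range(500))
        assert hits >= 0.99 * 500

    def test_chi_one_edge_in_half_of_realizations(self):
        # Δθ = 1 rad, κκ' = 4: with μ = R/4 the ratio χ = RΔθ/(μκκ') is exactly 1
        mu = (2 / (2 * np.pi)) / 4.0
        p = ModelParams(n_nodes=2, beta=2.0, mu=mu)
        nodes = NodeTable(theta=[0.0, 1.0], kappa=[2.0, 2.0], sigma=[2.0, 2.0])
        rng = np.random.default_rng(1)
        n_rep = 10_000
        hits = sum(generate_topology(nodes, p, rng).n_edges for _ in range(n_rep))
        se = np.sqrt(0.25 / n_rep)
        assert abs(hits / n_rep - 0.5) < 2 * se + 1e-9

    def test_mean_degree_matches_calibration(self):
        p = ModelParams(n_nodes=1000, seed=4)
        target = kappa_law_mean(p.kappa_law, p.n_nodes)
        nodes = sample_nodes(p)
        from dataclasses import replace

        pm = replace(p, mu=calibrate_mu(p, target, nodes))
        rng = np.random.default_rng(2)
        means = [generate_topology(nodes, pm, rng).degrees().mean() for _ in range(20)]
        assert abs(np.mean(means) - target) / target < 0.05


class TestAssignWeights:
    def test_tau_zero_sigma_equals_kappa_gives_unit_weights(self):
        p = ModelParams(n_nodes=64, tau=0.0, nu=1.0, a=1.0, eta=1.0, seed=5)
        nodes = sample_nodes(p)
        rng = np.random.default_rng(0)
        topo = generate_topology(nodes, p, rng)
        net = assign_weights(topo, nodes, p)
        np.testing.assert_allclose(net.weights, 1.0)

    def test_hand_evaluated_weight(self):
        # τ=0.5, ν=1, σ=κ=2 both, d=4 → ω = 4/(4^0.5 · 4^0.5) = 1
        p = ModelParams(n_nodes=10, tau=0.5, nu=1.0, mu=1.0)
        dtheta = 4.0 / p.radius
        nodes = NodeTable(theta=[0.0, dtheta], kappa=[2.0, 2.0], sigma=[2.0, 2.0])
        topo = generate_topology(
            NodeTable(theta=[0.0, 0.0], kappa=[1e9, 1e9], sigma=[1.0, 1.0]), p,
            np.random.default_rng(0),
        )  # guaranteed single edge
        net = assign_weights(topo, nodes, p)
        assert net.weights[0] == pytest.approx(1.0)

    def test_linear_in_nu(self):
        from dataclasses import replace

        p = ModelParams(n_nodes=64, tau=0.3, seed=6)
        nodes = sample_nodes(p)
        topo = generate_topology(nodes, p, np.random.default_rng(0))
        w1 = assign_weights(topo, nodes, p).weights
        w2 = assign_weights(topo, nodes, replace(p, nu=2.0)).weights
        np.testing.assert_allclose(w2, 2.0 * w1)

    def test_weight_decreases_with_distance_at_fixed_kappa(self):
        # constant κ and σ: Spearman(weight, distance) must be −1 for τ > 0
        p = ModelParams(
            n_nodes=256, tau=0.5, seed=8, kappa_law={"type": "constant", "value": 12.0}
        )
        nodes = sample_nodes(p)
        from dataclasses import replace

        pm = replace(p, mu=calibrate_mu(p, 10.0, nodes))
        topo = generate_topology(nodes, pm, np.random.default_rng(3))
        net = assign_weights(topo, nodes, pm)
        from grwnet.network import angular_separation

        d = angular_separation(nodes.theta[net.edges[:, 0]], nodes.theta[net.edges[:, 1]])
        rho = sps.spearmanr(net.weights, d).statistic
        assert rho == pytest.approx(-1.0)


class TestCalibrateNu:
    def test_mean_strength_matches_mean_sigma(self):
        p = ModelParams(n_nodes=2000, seed=11, tau=0.5)
        target = kappa_law_mean(p.kappa_law, p.n_nodes)
        net, nodes, fitted = generate_network(p, target_mean_degree=target)
        assert abs(net.strengths().mean() - nodes.sigma.mean()) / nodes.sigma.mean() < 0.05

    def test_doubling_nu_doubles_mean_strength(self):
        from dataclasses import replace

        p = ModelParams(n_nodes=256, seed=13, tau=0.4)
        nodes = sample_nodes(p)
        topo = generate_topology(nodes, p, np.random.default_rng(0))
        nu = calibrate_nu(topo, nodes, p)
        s1 = assign_weights(topo, nodes, replace(p, nu=nu)).strengths().mean()
        s2 = assign_weights(topo, nodes, replace(p, nu=2 * nu)).strengths().mean()
        assert s2 / s1 == pytest.approx(2.0)

    def test_empty_network_raises(self):
        p = ModelParams(n_nodes=4)
        nodes = sample_nodes(p)
        empty = generate_topology(
            NodeTable(theta=nodes.theta, kappa=np.full(4, 1e-9), sigma=nodes.sigma),
            p, np.random.default_rng(0),
        )
        with pytest.raises(CalibrationError):
            calibrate_nu(empty, nodes, p)


class TestDeterminism:
    def test_identical_seeds_identical_networks(self):
        p = ModelParams(n_nodes=300, seed=77, tau=0.5)
        n1, _, _ = generate_network(p, target_mean_degree=10.0)
        n2, _, _ = generate_network(p, target_mean_degree=10.0)
        assert np.array_equal(n1.edges, n2.edges)
        assert np.array_equal(n1.weights, n2.weights)


class TestCohort:
    def test_shared_node_set_and_lengths(self):
        p = ModelParams(n_nodes=120, seed=21)
        cohort = generate_cohort(p, 5, subject_variability=0.1, target_mean_degree=8.0)
        assert cohort.n_subjects == 5
        assert all(s.n_nodes == 120 for s in cohort.subjects)
        # length proxy depends only on the shared positions
        l1 = cohort.edge_length(np.array([0]), np.array([1]))
        l2 = cohort.edge_length(np.array([0]), np.array([1]))
        assert l1 == l2

    def test_zero_variability_same_seed_identical_subjects(self):
        p = ModelParams(n_nodes=100, seed=22)
        cohort = generate_cohort(
            p, 3, subject_variability=0.0, target_mean_degree=8.0, subject_seeds=[5, 5, 5]
        )
        a, b, c = cohort.subjects
        assert np.array_equal(a.edges, b.edges) and np.array_equal(b.edges, c.edges)
        assert np.array_equal(a.weights, c.weights)

    def test_deterministic_given_seed(self):
        p = ModelParams(n_nodes=80, seed=23)
        c1 = generate_cohort(p, 3, target_mean_degree=6.0)
        c2 = generate_cohort(p, 3, target_mean_degree=6.0)
        for a, b in zip(c1.subjects, c2.subjects):
            assert np.array_equal(a.edges, b.edges)
            assert np.array_equal(a.weights, b.weights)


def test_expected_mean_degree_matches_ring_oracle():
    """On a deterministic ring geometry the pair-sum expectation agrees with
    a brute-force loop over pairs."""
    nodes = ring_nodes(40)
    p = ModelParams(n_nodes=40, beta=3.0, mu=0.02)
    brute = 0.0
    for i in range(40):
        for j in range(i + 1, 40):
            brute += float(
                connection_probability(nodes.theta[i], nodes.theta[j], 10.0, 10.0, p)
            )
    assert expected_mean_degree(nodes, p) == pytest.approx(2 * brute / 40, rel=1e-12)
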