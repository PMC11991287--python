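"""Weighted geometric soft configuration model (WS1) generator.

Topology follows the S1 model: nodes live on a circle of radius R = N/(2π)
with hidden degrees κ, and each pair connects independently with the
gravity-law probability

    p_ij = 1 / (1 + χ_ij^β),   χ_ij = d_ij / (μ κ_i κ_j),   d_ij = R Δθ_ij,

where β > 1 sets clustering (topology–geometry coupling) and μ the average
degree.  Weights couple to the same geometry through hidden strengths
σ = a κ^η:

    ω_ij = ε_ij ν σ_i σ_j / ((κ_i κ_j)^{1-τ} d_ij^τ),   0 ≤ τ < 1,

so τ = 0 decouples weights from geometry (pure degree dependence) and τ → 1
makes them maximally distance-dependent.  ε is unit-mean noise; the default
is the noiseless ε ≡ 1 variant.  ν is a free scale fixed by calibration so
that realized mean strength matches mean hidden strength, ⟨s⟩ = ⟨σ⟩.

Sublinear η (slightly below 1) reproduces the connectome regime where hub
strength grows slower than hub degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import optimize

from .network import Cohort, NodeTable, WeightedNetwork, angular_separation

__all__ = [
    "ModelParams",
    "ParameterError",
    "CalibrationError",
    "sample_nodes",
    "connection_probability",
    "expected_mean_degree",
    "calibrate_mu",
    "generate_topology",
    "assign_weights",
    "calibrate_nu",
    "generate_network",
    "generate_cohort",
    "truncated_powerlaw_mean",
    "kappa_law_mean",
]


class ParameterError(ValueError):
    """Invalid model parameter specification."""


class CalibrationError(RuntimeError):
    """Calibration failed to converge; message carries diagnostics."""


# default hidden-degree law: power law with the natural cutoff
# κ_c = κ_0 N^{1/(γ-1)} (kappa_max=None), the canonical S1 ensemble.  κ is an
# expected degree, so analyses target ⟨k⟩ = ⟨κ⟩ (≈14 at n=4096) by default.
DEFAULT_KAPPA_LAW: Mapping[str, Any] = {
    "type": "powerlaw",
    "gamma": 2.5,
    "kappa_min": 5.0,
    "kappa_max": None,
}


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the WS1 generator.

    beta > 1, mu > 0, 0 ≤ tau < 1, nu > 0, a > 0, eta > 0.  ``kappa_law`` is
    either a power-law spec ``{"type": "powerlaw", "gamma", "kappa_min",
    "kappa_max"}``, a constant ``{"type": "constant", "value"}``, or an
    explicit list ``{"type": "list", "values": [...]}`` so empirical degree
    sequences can be injected.  ``noise_model`` is "noiseless" (ε ≡ 1) or
    ``{"type": "gamma", "shape": ...}`` for unit-mean gamma noise.
    """

    n_nodes: int
    beta: float = 2.5
    mu: float = 0.01
    tau: float = 0.5
    nu: float = 1.0
    a: float = 1.0
    eta: float = 0.9
    kappa_law: Mapping[str, Any] = field(default_factory=lambda: dict(DEFAULT_KAPPA_LAW))
    noise_model: Any = "noiseless"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ParameterError("n_nodes must be a positive integer")
        if not self.beta > 1:
            raise ParameterError("beta must exceed 1")
        if not (0.0 <= self.tau < 1.0):
            raise ParameterError("tau must lie in [0, 1)")
        for name in ("mu", "nu", "a", "eta"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")

    @property
    def radius(self) -> float:
        """Similarity-circle radius R = N / (2π)."""
        return self.n_nodes / (2.0 * np.pi)


def truncated_powerlaw_mean(gamma: float, kappa_min: float, kappa_max: float) -> float:
    """Closed-form mean of the truncated power law p(κ) ∝ κ^{-γ} on [κ0, κc]."""
    g1, g2 = 1.0 - gamma, 2.0 - gamma
    if abs(g1) < 1e-12 or abs(g2) < 1e-12:
        raise ParameterError("gamma = 1 or 2 needs the logarithmic special case; unsupported")
    return (g1 / g2) * (kappa_max**g2 - kappa_min**g2) / (kappa_max**g1 - kappa_min**g1)


def kappa_law_mean(law: Mapping[str, Any], n: int) -> float:
    """Analytic mean of a hidden-degree law (the natural ⟨k⟩ target)."""
    kind = law.get("type")
    if kind == "powerlaw":
        k0 = float(law["kappa_min"])
        gamma = float(law["gamma"])
        kc = k0 * n ** (1.0 / (gamma - 1.0)) if law["kappa_max"] is None else float(law["kappa_max"])
        return truncated_powerlaw_mean(gamma, k0, kc)
    if kind == "constant":
        return float(law["value"])
    if kind == "list":
        return float(np.mean(law["values"]))
    raise ParameterError(f"unknown kappa_law type {kind!r}")


def _sample_kappa(law: Mapping[str, Any], n: int, rng: np.random.Generator) -> np.ndarray:
    if not isinstance(law, Mapping) or "type" not in law:
        raise ParameterError("kappa_law must be a mapping with a 'type' key")
    kind = law["type"]
    if kind == "powerlaw":
        try:
            gamma = float(law["gamma"])
            k0 = float(law["kappa_min"])
            kc_raw = law["kappa_max"]
        except KeyError as exc:
            raise ParameterError(f"powerlaw kappa_law missing key {exc}") from exc
        # kappa_max=None → natural cutoff κ_0 N^{1/(γ-1)}
        kc = k0 * n ** (1.0 / (gamma - 1.0)) if kc_raw is None else float(kc_raw)
        if not (0 < k0 < kc) or gamma <= 1:
            raise ParameterError("need 0 < kappa_min < kappa_max and gamma > 1")
        u = rng.random(n)
        g1 = 1.0 - gamma
        return (k0**g1 + u * (kc**g1 - k0**g1)) ** (1.0 / g1)
    if kind == "constant":
        v = float(law["value"])
        if v <= 0:
            raise ParameterError("constant kappa must be positive")
        return np.full(n, v)
    if kind == "list":
        vals = np.asarray(law["values"], dtype=np.float64)
        if len(vals) != n:
            raise ParameterError(f"explicit kappa list has {len(vals)} entries, need {n}")
        if np.any(vals <= 0):
            raise ParameterError("explicit kappa values must be positive")
        return vals.copy()
    raise ParameterError(f"unknown kappa_law type {kind!r}")


def sample_nodes(params: ModelParams, rng: np.random.Generator | None = None) -> NodeTable:
    """Sample node coordinates: θ uniform on the circle, κ from ``kappa_law``, σ = aκ^η.

    Exactly coincident angles are re-jittered at machine scale so that
    pairwise distances are strictly positive (the weight law diverges at
    d = 0 for τ > 0).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = params.n_nodes
    theta = rng.random(n) * 2.0 * np.pi
    # uniform doubles collide with negligible probability, but the weight law
    # cannot tolerate d = 0, so enforce distinctness deterministically
    while len(np.unique(theta)) < n:
        dup = np.ones(n, dtype=bool)
        dup[np.unique(theta, return_index=True)[1]] = False
        theta[dup] += (rng.random(dup.sum()) + 0.5) * 1e-12
        theta = np.mod(theta, 2.0 * np.pi)
    kappa = _sample_kappa(params.kappa_law, n, rng)
    sigma = params.a * kappa**params.eta
    return NodeTable(theta=theta, kappa=kappa, sigma=sigma)


def connection_probability(
    theta_i: np.ndarray,
    theta_j: np.ndarray,
    kappa_i: np.ndarray,
    kappa_j: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Gravity-law link probability p = 1/(1 + χ^β) with χ = RΔθ/(μκκ')."""
    kappa_i, kappa_j = np.asarray(kappa_i, float), np.asarray(kappa_j, float)
    if np.any(kappa_i <= 0) or np.any(kappa_j <= 0):
        raise ParameterError("hidden degrees must be strictly positive")
    d = params.radius * angular_separation(theta_i, theta_j)
    chi = d / (params.mu * kappa_i * kappa_j)
    # overflow-safe: p = exp(-logaddexp(0, β log χ))
    with np.errstate(divide="ignore"):
        logchi = np.log(chi)
    return np.exp(-np.logaddexp(0.0, params.beta * logchi))


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def expected_mean_degree(nodes: NodeTable, params: ModelParams, mu: float | None = None) -> float:
    """Exact ensemble-mean degree given the sampled coordinates: (2/N) Σ_{i<j} p_ij."""
    p = params if mu is None else replace(params, mu=mu)
    n = len(nodes)
    iu, ju = _pair_indices(n)
    total = 0.0
    # chunked to bound peak memory at large n
    step = 2_000_000
    for s in range(0, len(iu), step):
        sl = slice(s, s + step)
        pij = connection_probability(
            nodes.theta[iu[sl]], nodes.theta[ju[sl]], nodes.kappa[iu[sl]], nodes.kappa[ju[sl]], p
        )
        total += float(pij.sum())
    return 2.0 * total / n


def mu_closed_form(beta: float, mean_degree: float) -> float:
    """Standard S1 closed form μ = β sin(π/β) / (2π⟨k⟩) (N → ∞, no cutoffs)."""
    return beta * math.sin(math.pi / beta) / (2.0 * math.pi * mean_degree)


def calibrate_mu(
    params: ModelParams,
    target_mean_degree: float,
    nodes: NodeTable | None = None,
) -> float:
    """Find μ so that the ensemble mean degree equals ``target_mean_degree``.

    Starts from the infinite-size closed form and Brent-corrects against the
    exact expected mean degree for the given (or seed-sampled) coordinates;
    the correction absorbs finite-size and κ-cutoff effects.  Deterministic
    for fixed inputs.
    """
    if target_mean_degree <= 0:
        raise ParameterError("target mean degree must be positive")
    if target_mean_degree >= params.n_nodes - 1:
        raise ParameterError("target mean degree infeasible for n_nodes")
    if nodes is None:
        nodes = sample_nodes(params)
    mu0 = mu_closed_form(params.beta, target_mean_degree)

    def gap(log_mu: float) -> float:
        return expected_mean_degree(nodes, params, mu=math.exp(log_mu)) - target_mean_degree

    lo, hi = math.log(mu0), math.log(mu0)
    glo, ghi = gap(lo), gap(hi)
    for _ in range(60):
        if glo < 0 < ghi or glo == 0 or ghi == 0:
            break
        if glo > 0:  # expected degree too high at lo → shrink μ
            lo -= 1.0
            glo = gap(lo)
        if ghi < 0:
            hi += 1.0
            ghi = gap(hi)
    else:
        raise CalibrationError(
            f"could not bracket mu: gap({lo:.2f})={glo:.3g}, gap({hi:.2f})={ghi:.3g}"
        )
    if glo == 0:
        return math.exp(lo)
    if ghi == 0:
        return math.exp(hi)
    log_mu = optimize.brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12)
    return math.exp(log_mu)


def generate_topology(
    nodes: NodeTable, params: ModelParams, rng: np.random.Generator
) -> WeightedNetwork:
    """Independent Bernoulli draw per node pair with the gravity-law probability.

    Returned weights are a placeholder 1.0 per edge; use :func:`assign_weights`.
    """
    n = len(nodes)
    iu, ju = _pair_indices(n)
    keep_chunks = []
    step = 2_000_000
    for s in range(0, len(iu), step):
        sl = slice(s, s + step)
        pij = connection_probability(
            nodes.theta[iu[sl]], nodes.theta[ju[sl]], nodes.kappa[iu[sl]], nodes.kappa[ju[sl]], params
        )
        keep_chunks.append(rng.random(len(pij)) < pij)
    keep = np.concatenate(keep_chunks) if keep_chunks else np.zeros(0, bool)
    edges = np.column_stack([iu[keep], ju[keep]])
    return WeightedNetwork(n, edges, np.ones(edges.shape[0]))


def assign_weights(
    network: WeightedNetwork,
    nodes: NodeTable,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> WeightedNetwork:
    """Attach geometric weights ω = ε ν σσ' / ((κκ')^{1-τ} d^τ) to every edge."""
    i, j = network.edges[:, 0], network.edges[:, 1]
    d = params.radius * angular_separation(nodes.theta[i], nodes.theta[j])
    if network.n_edges and params.tau > 0 and np.any(d <= 0):
        raise ParameterError("coincident node angles give d = 0; weight law diverges")
    if params.noise_model == "noiseless":
        eps = 1.0
    elif isinstance(params.noise_model, Mapping) and params.noise_model.get("type") == "gamma":
        shape = float(params.noise_model["shape"])
        if rng is None:
            raise ParameterError("gamma noise requires an rng")
        eps = rng.gamma(shape, 1.0 / shape, size=network.n_edges)  # unit mean
    else:
        raise ParameterError(f"unknown noise_model {params.noise_model!r}")
    kk = nodes.kappa[i] * nodes.kappa[j]
    w = eps * params.nu * nodes.sigma[i] * nodes.sigma[j] / (kk ** (1.0 - params.tau))
    if params.tau > 0:
        w = w / d**params.tau
    return WeightedNetwork(network.n_nodes, network.edges, w, list(network.node_ids))


def calibrate_nu(
    network: WeightedNetwork, nodes: NodeTable, params: ModelParams
) -> float:
    """Choose ν so that the realized mean strength equals the mean hidden strength.

    ⟨s⟩ is exactly linear in ν, so ν = ⟨σ⟩ / ⟨s⟩|_{ν=1} in closed form on the
    given topology.
    """
    if network.n_edges == 0:
        raise CalibrationError("cannot calibrate nu on an empty edge set")
    w1 = assign_weights(network, nodes, replace(params, nu=1.0, noise_model="noiseless"))
    mean_s = 2.0 * float(w1.weights.sum()) / network.n_nodes
    return float(nodes.sigma.mean() / mean_s)


def generate_network(
    params: ModelParams,
    target_mean_degree: float | None = None,
    rng: np.random.Generator | None = None,
    nodes: NodeTable | None = None,
    calibrate: bool = True,
) -> tuple[WeightedNetwork, NodeTable, ModelParams]:
    """One-call generation: nodes → μ calibration → topology → ν calibration → weights.

    Returns the weighted network, the node table and the parameter set with
    the calibrated μ and ν filled in.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if nodes is None:
        nodes = sample_nodes(params, rng)
    if calibrate and target_mean_degree is not None:
        params = replace(params, mu=calibrate_mu(params, target_mean_degree, nodes))
    topo = generate_topology(nodes, params, rng)
    if calibrate and topo.n_edges:
        params = replace(params, nu=calibrate_nu(topo, nodes, params))
    net = assign_weights(topo, nodes, params, rng)
    return net, nodes, params


def _cohort_positions(theta: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Euclidean layout: nodes on a 70 mm-radius ring (cortex scale)
    with ±6 mm out-of-plane jitter; hemisphere = sign of the y half-plane.

    Euclidean distance then grows with angular separation, which is what the
    distance-dependent consensus stage needs from a length proxy.
    """
    r_mm = 70.0
    x = r_mm * np.cos(theta)
    y = r_mm * np.sin(theta)
    z = rng.normal(0.0, 6.0, size=len(theta))
    hemi = np.where(np.sin(theta) >= 0.0, "L", "R")
    return np.column_stack([x, y, z]), hemi


def generate_cohort(
    params: ModelParams,
    n_subjects: int,
    subject_variability: float = 0.1,
    rng: np.random.Generator | None = None,
    target_mean_degree: float | None = None,
    subject_seeds: Sequence[int] | None = None,
) -> Cohort:
    """Multi-subject cohort over one shared node set.

    All subjects share θ, Euclidean positions and hemisphere labels; each
    subject re-draws its topology and weights after a multiplicative
    lognormal jitter of κ (scale ``subject_variability``), emulating
    subject-level fluctuation around a common geometric backbone.  Passing
    explicit ``subject_seeds`` (e.g. all equal, with variability 0) gives
    replicated subjects.
    """
    if n_subjects < 2:
        raise ParameterError("a cohort needs at least two subjects")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    base_nodes = sample_nodes(params, rng)
    xyz, hemi = _cohort_positions(base_nodes.theta, rng)
    if target_mean_degree is not None:
        params = replace(params, mu=calibrate_mu(params, target_mean_degree, base_nodes))
    if subject_seeds is None:
        subject_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_subjects)]
    elif len(subject_seeds) != n_subjects:
        raise ParameterError("subject_seeds length must equal n_subjects")
    subjects = []
    for seed in subject_seeds:
        srng = np.random.default_rng(int(seed))
        if subject_variability > 0:
            jitter = np.exp(srng.normal(0.0, subject_variability, size=len(base_nodes)))
        else:
            jitter = 1.0
        kappa_s = base_nodes.kappa * jitter
        nodes_s = NodeTable(
            theta=base_nodes.theta,
            kappa=kappa_s,
            sigma=params.a * kappa_s**params.eta,
            xyz=xyz,
            hemisphere=hemi,
        )
        topo = generate_topology(nodes_s, params, srng)
        nu_s = calibrate_nu(topo, nodes_s, params) if topo.n_edges else params.nu
        net = assign_weights(topo, nodes_s, replace(params, nu=nu_s), srng)
        subjects.append(net)
    shared = NodeTable(
        theta=base_nodes.theta,
        kappa=base_nodes.kappa,
        sigma=base_nodes.sigma,
        xyz=xyz,
        hemisphere=hemi,
    )
    return Cohort(nodes=shared, subjects=subjects)
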