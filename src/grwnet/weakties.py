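"""Weak-ties analysis: modules, weight/confidence filters, ρ_inter spectra.

The weak-ties statistic is the density of intermodular links RE_n in the
sub-network that keeps the n% weakest (lowest-weight or lowest-confidence)
edges, normalized by the unfiltered density RE_100:

    ρ_inter(n) = RE_n / RE_100,  ρ_inter(100) = 1.

A decreasing spectrum means weak ties concentrate between modules — the
weak-ties hypothesis.  The confidence variant uses the disparity-filter
significance: for an edge seen from an endpoint of degree k with normalized
weight w/s, the probability of a null weight at least as large is

    α = 1 − (k−1) ∫₀^{w/s} (1−x)^{k−2} dx = (1 − w/s)^{k−1},

and confidence = 1 − α.  An undirected edge carries one α per endpoint; the
edge-level value is the minimum α (maximum confidence) of the two, the
conservative convention of the disparity-filter literature.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import numpy as np

from .network import WeightedNetwork

__all__ = [
    "Partition",
    "Spectrum",
    "detect_modules",
    "modularity",
    "global_weight_filter",
    "alpha_closed_form",
    "edge_confidence",
    "confidence_filter",
    "intermodular_density",
    "weak_ties_spectrum",
    "intra_inter_mean_weights",
]


@dataclass
class Partition:
    """Node → module assignment over all nodes of a network."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class Spectrum:
    """ρ_inter values over retained-edge percentages; NaN marks undefined points."""

    percents: np.ndarray
    rho_inter: np.ndarray
    undefined: bool = False


def detect_modules(
    network: WeightedNetwork, mode: str = "unweighted", seed: int = 0
) -> Partition:
    """Louvain community detection (igraph multilevel), deterministic per seed.

    ``mode="unweighted"`` ignores weights so the partition is not directly
    influenced by them; ``mode="weighted"`` maximizes weighted modularity.
    Components are handled natively by the algorithm.
    """
    if network.n_nodes == 0 or network.n_edges == 0:
        raise ValueError("module detection needs a non-empty network")
    if mode not in ("unweighted", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    g = network.to_igraph(weighted=(mode == "weighted"))
    state = _pyrandom.getstate()
    try:
        # python-igraph draws from Python's random module
        _pyrandom.seed(seed)
        part = g.community_multilevel(
            weights="weight" if mode == "weighted" else None
        )
    finally:
        _pyrandom.setstate(state)
    return Partition(np.asarray(part.membership, dtype=np.int64))


def modularity(network: WeightedNetwork, partition: Partition, weighted: bool = False) -> float:
    """Newman modularity of a partition (unweighted by default, as for detection)."""
    g = network.to_igraph(weighted=weighted)
    return float(
        g.modularity(partition.labels.tolist(), weights="weight" if weighted else None)
    )


def _retain_count(n_edges: int, percent: float) -> int:
    if not (0.0 < percent <= 100.0):
        raise ValueError("percent must lie in (0, 100]")
    return int(np.ceil(percent / 100.0 * n_edges))


def global_weight_filter(network: WeightedNetwork, percent: float) -> WeightedNetwork:
    """Keep the ⌈n% · E⌉ lowest-weight edges (nodes unchanged).

    Ties at the cutoff are broken by the canonical edge index (stable), so the
    retained sets are nested across thresholds.
    """
    m = _retain_count(network.n_edges, percent)
    order = np.lexsort((np.arange(network.n_edges), network.weights))
    return network.with_edges(np.sort(order[:m]))


def alpha_closed_form(w_over_s: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Disparity-filter significance α = (1 − w/s)^{k−1} for endpoint degree k ≥ 2.

    For k = 1 the statistic is undefined (a single link carries no local
    heterogeneity information); by convention α = 1, never significant.
    """
    w_over_s = np.asarray(w_over_s, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if np.any(w_over_s < 0) or np.any(w_over_s > 1 + 1e-12):
        raise ValueError("normalized weights must lie in [0, 1]; w > s signals corrupt strengths")
    alpha = np.power(np.clip(1.0 - w_over_s, 0.0, 1.0), np.maximum(k, 2.0) - 1.0)
    return np.where(k < 2, 1.0, alpha)


def edge_confidence(network: WeightedNetwork) -> dict[str, np.ndarray]:
    """Per-edge significance: α from each endpoint plus the edge-level
    α = min(α_i, α_j) and confidence 1 − α."""
    s = network.strengths()
    k = network.degrees()
    i, j = network.edges[:, 0], network.edges[:, 1]
    a_i = alpha_closed_form(network.weights / s[i], k[i])
    a_j = alpha_closed_form(network.weights / s[j], k[j])
    alpha = np.minimum(a_i, a_j)
    return {"alpha_i": a_i, "alpha_j": a_j, "alpha": alpha, "confidence": 1.0 - alpha}


def confidence_filter(network: WeightedNetwork, percent: float) -> WeightedNetwork:
    """Keep the ⌈n% · E⌉ edges of lowest confidence (least significant weights)."""
    m = _retain_count(network.n_edges, percent)
    conf = edge_confidence(network)["confidence"]
    order = np.lexsort((np.arange(network.n_edges), conf))
    return network.with_edges(np.sort(order[:m]))


def intermodular_density(network: WeightedNetwork, partition: Partition) -> float:
    """Fraction of edges whose endpoints lie in different modules; NaN if no edges."""
    if len(partition.labels) != network.n_nodes:
        raise ValueError("partition must cover the network's node set")
    if network.n_edges == 0:
        return float("nan")
    lab = partition.labels
    inter = lab[network.edges[:, 0]] != lab[network.edges[:, 1]]
    return float(inter.mean())


def weak_ties_spectrum(
    network: WeightedNetwork,
    partition: Partition,
    filter: str = "weight",
    percents: np.ndarray | None = None,
) -> Spectrum:
    """ρ_inter(n) over a grid of retained percentages for one filter.

    The partition comes from the *unfiltered* network.  If the partition has
    a single module there are no intermodular links and the spectrum is
    flagged undefined (all NaN).
    """
    if percents is None:
        percents = np.array([1, 2, 5, 10, 25, 50, 75, 100], dtype=float)
    percents = np.asarray(percents, dtype=float)
    if 100.0 not in percents:
        raise ValueError("percents must include 100 (the normalization point)")
    filt = {"weight": global_weight_filter, "confidence": confidence_filter}.get(filter)
    if filt is None:
        raise ValueError(f"unknown filter {filter!r}")
    re100 = intermodular_density(network, partition)
    if not np.isfinite(re100) or re100 == 0.0:
        return Spectrum(percents, np.full(len(percents), np.nan), undefined=True)
    rho = np.array(
        [intermodular_density(filt(network, p), partition) / re100 for p in percents]
    )
    return Spectrum(percents, rho)


def intra_inter_mean_weights(
    network: WeightedNetwork, partition: Partition
) -> tuple[float, float]:
    """(intra, inter) mean weights.

    Intra: unweighted mean over modules of each module's mean internal edge
    weight (modules without internal edges are skipped).  Inter: plain mean
    over all intermodular edges.
    """
    lab = partition.labels
    if partition.n_modules < 2:
        raise ValueError("need at least two modules to compare intra vs inter weights")
    li, lj = lab[network.edges[:, 0]], lab[network.edges[:, 1]]
    intra_means = []
    for mod in np.unique(lab):
        m = (li == mod) & (lj == mod)
        if m.any():
            intra_means.append(network.weights[m].mean())
    inter_mask = li != lj
    if not intra_means or not inter_mask.any():
        raise ValueError("need intramodular and intermodular edges")
    return float(np.mean(intra_means)), float(network.weights[inter_mask].mean())
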