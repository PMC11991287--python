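"""Surrogate (null-model) constructions for the multiscale weight analysis.

CP-WR (coordinate-preserving weight reshuffling) keeps the geometry and the
topology and randomly permutes the edge weights, decoupling weights from
both.  CR-GRW (coordinate-reshuffling renormalization) permutes the angular
positions of the nodes before running the renormalization flow, so the
coarse-graining no longer respects the latent geometry; layer 0 is left
untouched.  Stochastic surrogates are averaged over independent
realizations (10 by default).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .network import LayerStack, NodeTable, WeightedNetwork
from .renormalize import renormalize_flow

__all__ = ["cp_wr", "cp_wr_stack", "cr_grw", "ensemble_average"]


def cp_wr(network: WeightedNetwork, seed: int = 0) -> WeightedNetwork:
    """Weight-reshuffled surrogate: identical edge set, permuted weight multiset."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(network.n_edges)
    return WeightedNetwork(
        network.n_nodes, network.edges.copy(), network.weights[perm], list(network.node_ids)
    )


def cp_wr_stack(stack: LayerStack, seed: int = 0) -> LayerStack:
    """CP-WR applied to each layer independently (per-layer reshuffling)."""
    rng = np.random.default_rng(seed)
    layers = [cp_wr(g, seed=int(rng.integers(0, 2**31 - 1))) for g in stack.layers]
    return LayerStack(layers=layers, maps=[m.copy() for m in stack.maps],
                      node_tables=stack.node_tables)


def cr_grw(
    network: WeightedNetwork,
    nodes: NodeTable,
    r: int,
    n_steps: int,
    seed: int = 0,
) -> LayerStack:
    """Renormalization flow after a uniform random permutation of the angular
    coordinates.  Layer 0 keeps the original topology and weights; only the
    block structure of the coarse-graining is randomized."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(nodes))
    shuffled = NodeTable(
        theta=nodes.theta[perm],
        kappa=nodes.kappa,
        sigma=nodes.sigma,
        xyz=nodes.xyz,
        hemisphere=nodes.hemisphere,
    )
    return renormalize_flow(network, shuffled, r, n_steps)


def ensemble_average(
    procedure: Callable[[int], np.ndarray],
    seeds: Sequence[int] | None = None,
    n_realizations: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation of curves returned by
    ``procedure(seed)`` over realizations.  All curves must share one grid
    (equal length); a mismatch raises."""
    if seeds is None:
        seeds = list(range(n_realizations))
    curves = [np.asarray(procedure(int(s)), dtype=float) for s in seeds]
    shapes = {c.shape for c in curves}
    if len(shapes) != 1:
        raise ValueError(f"procedure returned curves on inconsistent grids: {shapes}")
    arr = np.stack(curves)
    return arr.mean(axis=0), arr.std(axis=0)
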