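# grwnet — multiscale self-similarity of weighted geometric networks

`grwnet` studies how link *weights* organize across length scales in
connectome-like networks. Brain structural networks reconstructed at several
parcellation resolutions show the same weighted statistics at every scale —
weight and strength distributions, the strength–degree relation, the local
weight disparity, and the placement of weak ties between modules. This
package reproduces that phenomenology end to end on synthetic data: a
weighted geometric network generator, a geometric renormalization transform
that unfolds one network into a stack of coarser self-similar layers, the
weighted observables and null models used to quantify the effect, a
likelihood-based latent-geometry inference, and a distance-dependent
consensus group-representative for multi-subject cohorts.

## The model

Topology follows the geometric soft configuration model (S1): node *i* has
an angular position θᵢ on a circle of radius R = N/2π and a hidden degree
κᵢ; a pair connects with the gravity-law probability

    p_ij = 1 / (1 + χ_ij^β),   χ_ij = d_ij / (μ κ_i κ_j),   d_ij = R·Δθ_ij,

where β > 1 sets clustering and μ the mean degree. Weights couple to the
same latent geometry (WS1): with hidden strengths σ = a κ^η,

    ω_ij = ε_ij ν σ_i σ_j / ((κ_i κ_j)^{1−τ} d_ij^τ),   0 ≤ τ < 1,

so τ interpolates between degree-driven (τ = 0) and distance-driven weights.
Scales are connected by the sup-GRW transform: r angularly consecutive nodes
merge into a supernode, two supernodes link iff any of their members do, and
the superlink weight is the supremum of the member weights. The transform is
an exact semigroup: two r = 2 steps equal one r = 4 step.

Weak ties are quantified by ρ_inter(n): the fraction of intermodular links
among the n% lowest-weight (or lowest disparity-filter confidence) edges,
normalized by the unfiltered fraction. Local weight heterogeneity uses the
disparity Υ(k) = k Σⱼ (w_ij/s_i)² with its stick-breaking null band
E(k) = 2k/(k+1), V(k) per the flat-Dirichlet closed form.

## Worked example

```python
from grwnet.model import ModelParams, generate_network, kappa_law_mean
from grwnet.renormalize import renormalize_flow
from grwnet.weakties import detect_modules, weak_ties_spectrum
from grwnet.pipeline import cross_layer_ks
import numpy as np

params = ModelParams(n_nodes=1024, seed=1, beta=2.5, tau=0.5, eta=0.9)
net, nodes, fitted = generate_network(
    params, target_mean_degree=kappa_law_mean(params.kappa_law, 1024))
stack = renormalize_flow(net, nodes, r=2, n_steps=3, beta=fitted.beta)
print([g.n_nodes for g in stack.layers])
# [1024, 512, 256, 128]
print(np.round(np.diag(cross_layer_ks(stack, "weights"), 1), 3))
# [0.019 0.027 0.03 ]
part = detect_modules(stack.layers[0], seed=1)
spec = weak_ties_spectrum(stack.layers[0], part, "weight",
                          np.array([1, 10, 50, 100.0]))
print(np.round(spec.rho_inter, 2))
# [4.8  3.48 1.82 1.  ]
```

The KS distances near 0.02–0.03 say the rescaled weight distributions of
consecutive layers are statistically indistinguishable — the self-similarity
signature. ρ_inter(1%) ≈ 4.8 means the weakest 1% of links are ~5× more
likely to bridge modules than a typical link: the weak-ties effect, which
decays to 1 as the filter is relaxed.

The numbered scripts under `analysis/` run the full figure-level analyses
(self-similarity, weak-ties spectra, null-model contrasts, parameter
recovery, group-representative) and write their tables under `results/`.

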