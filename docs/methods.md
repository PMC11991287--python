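# Methods

This note documents the models, estimators and numerical choices behind
`grwnet`, and what the synthetic experiments do and do not establish.

## The weighted geometric model

The generator is the weighted geometric soft configuration model. Nodes
carry a uniform angular coordinate θ ∈ [0, 2π) on a circle of radius
R = N/2π, a hidden degree κ > 0 and a hidden strength σ = a κ^η. Pairs link
independently with p = 1/(1 + χ^β), χ = RΔθ/(μκκ′), and linked pairs carry
the weight ω = ε ν σσ′/((κκ′)^{1−τ} d^τ). Interpretation of the parameters:

| parameter | meaning | default | rationale |
|---|---|---|---|
| β | topology–geometry coupling; sets clustering | 2.5 | mid-range value giving connectome-like clustering; the inference recovers it from clustering alone |
| μ | mean-degree scale | calibrated | see below |
| τ | weight–geometry coupling | 0.5 | mid-range; weights fall with distance as in fiber-density weights, but degrees still matter |
| ν | global weight scale | calibrated so ⟨s⟩ = ⟨σ⟩ | the natural gauge: hidden strengths are then expected strengths |
| a, η | σ = aκ^η | 1, 0.9 | η slightly below 1 reproduces the sublinear strength–degree relation of connectomes (hubs weaker than their degree implies) |
| κ law | hidden-degree distribution | power law, γ = 2.5, κ₀ = 5, natural cutoff κ₀N^{1/(γ−1)} | the canonical ensemble of the geometric-renormalization literature; the natural cutoff keeps the law shape-invariant under coarse-graining. κ is an expected degree, so analyses target ⟨k⟩ = ⟨κ⟩ (≈14 at n = 4096) |
| ε | weight noise | 1 (noiseless) | the noiseless variant is the reference model; unit-mean gamma noise is available behind `noise_model` |

**μ calibration.** The infinite-size closed form μ = β sin(π/β)/(2π⟨k⟩)
misses finite-size and cutoff corrections by ~10–20%. `calibrate_mu` uses it
to initialize a Brent root-find on the *exact expected mean degree given the
sampled coordinates*, (2/N) Σ_{i<j} p_ij, which is deterministic and makes
the realized ensemble mean degree an unbiased hit on the target. `calibrate_nu`
is closed-form: ⟨s⟩ is linear in ν.

**Degenerate geometry.** Coincident angles would make the weight law diverge
for τ > 0; the sampler enforces distinct θ (machine-scale jitter on the
measure-zero event of a collision).

**Cohorts.** A cohort shares one node set (θ, Euclidean positions on a 70 mm
ring with ±6 mm out-of-plane jitter, hemisphere = half-plane). Subjects
re-draw topology and weights after multiplicative lognormal κ jitter
(σ_log = 0.1 by default) — fluctuation around a common geometric backbone.
The Euclidean positions exist only to give every node pair a fixed length
proxy, standing in for tractography fiber lengths; because positions are
shared, a connection's length is identical across subjects by construction.

## Renormalization (sup-GRW)

One step at resolution r: sort nodes by θ, cut into consecutive blocks of r
(the last block keeps the remainder), merge blocks into supernodes, connect
supernodes iff any member pair is connected, weight = supremum of member
weights; intra-block edges are absorbed. Supernode attributes: θ′ = mean of
member angles (any value inside the block's arc is equivalent),
κ′ = (Σκ^β)^{1/β} (the standard unweighted-renormalization merge, kept for
model-based continuation), σ′ = Σσ. Blocks are formed by node count, not by
equal arc. The semigroup identity ((r=2)∘(r=2) = (r=4)) is exact at the bit
level and tested on random instances.

Two observations about the flow on the default ensemble, measured by the
pipeline and worth stating plainly:

* the mean degree drifts up slowly (≈14 → 21 over three r = 2 steps) —
  consistent with the near-constant mean degree expected of the flow;
* the mean weight *decreases* ≈8% per step: with τ = 0.5 the strongest links
  are the shortest, and their absorption inside blocks outweighs the gain
  from taking suprema. On empirical connectomes the mean weight rises along
  the flow; the direction is data-dependent, so the pipeline reports
  per-layer means and the tests assert only the construction-level facts
  (weight multisets nest across layers; each superlink equals the supremum
  of its members).

**Self-similarity measurement.** Layer similarity is the two-sample KS
distance between rescaled (mean-1) weight, strength and degree samples of
consecutive layers, isolated nodes excluded. At the study conditions
(n = 4096, β = 2.5, τ = 0.5, 3 steps, 10 seeds) the ensemble means are
≈0.02 (weights), ≈0.05 (strengths) and ≈0.09–0.10 (degrees). Two caveats on
the degree number: the KS statistic has a finite-sample floor of ≈0.045 at
the smallest layer pair (1024 vs 512 nodes) even for identical
distributions, and the hard lower κ cutoff shifts slightly faster under the
κ′ merge than the mean degree does, which produces most of the residual.

## Weak ties

Modules come from igraph's Louvain (`community_multilevel`), run on the
*unweighted* graph by default so the partition is not shaped by the very
weights under test; the algorithm draws from Python's `random` module, which
the wrapper seeds and restores, making partitions deterministic per seed.
Resolution is fixed at 1; each layer is partitioned independently.

Two filters produce the weak-ties spectrum ρ_inter(n) = RE_n/RE_100:

* global weight filter — keep the ⌈n%·E⌉ lowest-weight edges;
* confidence filter — keep the lowest-confidence edges, where an edge's
  disparity-filter significance is α = (1 − w/s)^{k−1} evaluated from each
  endpoint and the edge takes the *minimum* α (maximum confidence) of the
  two — the conservative convention of the disparity-filter literature; a
  degree-1 endpoint contributes α = 1 (a single link carries no local
  heterogeneity information).

Ties in either ranking break by canonical edge index, so retained sets are
nested across thresholds and runs are reproducible. A single-module
partition leaves ρ_inter undefined and is flagged rather than reported as 0.
The intra-modular mean weight is the unweighted mean over modules of each
module's internal mean (modules without internal edges are skipped); the
inter-modular value is the plain mean over bridging edges.

## Disparity and its null

Υ(k) = k Σ (w/s)² per node, averaged per exact degree class. The null —
strength split uniformly at random, i.e. k−1 uniform points breaking [0, 1]
into k sticks — is the flat Dirichlet, giving E(k) = 2k/(k+1) and
V(k) = k²[(20+4k)/((k+1)(k+2)(k+3)) − 4/(k+1)²] (re-derived from Dirichlet
moments and cross-checked by Monte-Carlo stick breaking). A node is
compatible with the null below E + υV with υ = 2.

## Latent-geometry inference

* **Hidden degrees** — fixed-point iteration κ ← κ(k/E[k])^{1/2} (half-step
  damping in log space) matching angle-integrated expected degrees to
  observed degrees within 1%; the 1-D pair function E_Δθ[p](μκκ′) is
  tabulated on a 2048-knot log grid per iteration and interpolated.
* **β** — bisection in log β matching ensemble mean local clustering
  (igraph, zero-for-degree-1 convention) to the observed value within 5%,
  re-fitting μ and κ at each probe; boundary values are returned flagged
  when the target clustering is unreachable.
* **Angles** — spectral initialization (leading non-trivial eigenvector pair
  of D^{-1/2}AD^{-1/2} mapped to the circle), then per-node likelihood line
  search over 72 randomly offset grid angles, minimum 2 sweeps, stop when a
  sweep gains < 1e-4 log-likelihood. Each move is an argmax, so the
  likelihood is non-decreasing. Typical angular error after optimal
  rotation/reflection is ≈0.2 rad at n = 500.
* **τ** — grid search on {0, 0.05, …, 0.95} minimizing the L2 distance
  between log-binned mean-weight-vs-distance curves of the data and a
  20-replica model ensemble (topologies drawn once, reweighted per τ, ν
  re-calibrated each time). With true coordinates the estimate lands on the
  grid point nearest the truth; with *inferred* angles the scrambled short
  distances flatten the observed profile and bias τ̂ low — a known
  limitation of the simplified angle inference.
* **σ(κ)** — (a, η) by unweighted least squares of log s̄(k) on log k̄ over
  geometric degree bins (30 bins, bins with ≥3 nodes), the estimator also
  used for the strength–degree exponent. An exact power law is recovered
  exactly; single-degree-class networks return NaN, flagged.

**What recovery can and cannot achieve.** β, τ and η recover within the
tested tolerances at n = 1000. The *rank* correlation between κ̂ and the
true κ is capped near 0.8 at realistic density: any degree-based estimate is
monotone in k, and Spearman(k, κ) itself is limited by Poisson-level degree
noise (≈0.81 at ⟨κ⟩ ≈ 14; ≈0.94 even at an implausibly dense ⟨κ⟩ ≈ 77).
The cap is a property of the information in the data, not of the estimator.

**Replica validation.** `replica_validation` closes the loop — embed,
re-calibrate μ on the embedded coordinates, estimate τ, regenerate 100
replicas with σ = a κ̂^η̂ — and reports observed CCDFs against replica
mean ± 2 s.d. bands. First moments (mean degree/strength/weight) close
within a few percent. Pointwise band coverage is reported as a diagnostic
only: replicas re-draw Poisson-level degree noise around κ̂ ≈ k, so their
distributions are smeared relative to the single observed draw even under a
perfectly specified model, and the ensemble s.d. is tighter than that smear.

## Null models

* **CP-WR** — permute the weight multiset over the fixed edge set; applied
  per layer when given a stack. Exactly preserves topology and per-layer
  weight distributions (hence cross-layer weight overlap), while destroying
  weight–topology correlations: the strength–degree exponent moves to ≈1 and
  the weak-ties spectrum flattens to ≈1 at all thresholds.
* **CR-GRW** — permute angular coordinates, then renormalize; layer 0 is
  untouched. Coarse-graining no longer respects geometry, and the
  cross-layer strength/degree overlap breaks (KS ≈ 3× the flow's value at
  the study conditions).

Stochastic surrogate results are averaged over 10 realizations.

## Group-representative

Union edges are binned by cohort-average length into 22 equal-width bins
(equal-occupancy available behind a switch), separately for intra- and
inter-hemispheric edges so long inter-hemispheric links are not
under-represented. Each cell retains round-half-up(mean subject edge count)
edges, ranked by occurrence, then mean weight, then canonical index; each
retained edge receives a weight drawn from its subject-level weight multiset
(averaging is deliberately avoided — it would distort the weight
distribution). A cohort of identical subjects reproduces the subject network
exactly, and retained counts match the rounded per-cell means by
construction.

## Problem sizes and determinism

Default experiment sizes — n = 4096 networks, 3 renormalization steps, 10
seeds for ensembles, n = 1000 recovery networks, 40-subject cohorts at
n = 500 — were chosen to mirror the scale of multiresolution cortical
parcellations (~10³ nodes at the finest layer, five layers, ~40-subject
cohorts) while keeping every analysis deskside-fast. All stochastic stages
(generation, Louvain, surrogates, group weights) are driven by explicit
seeds; identical seeds give bit-identical networks.

## Known limitations

* The synthetic ensemble is noiseless (ε ≡ 1) and its weight heterogeneity
  is milder than the four-decade range of empirical fiber-density weights;
  phenomena driven by extreme weight tails are under-expressed.
* The simplified angle inference is a local likelihood ascent, not a full
  embedding tool; its residual angular error biases τ̂ low when τ > 0 and
  limits full-distribution replica validation (moments close, shapes smear).
* Hemisphere labels and Euclidean positions in cohorts are geometric
  conveniences (half-plane ring layout), not anatomical models.
* Degree distributions carry a hard lower κ cutoff whose image under the κ′
  merge drifts slightly; the degree-KS across layers is accordingly the
  least self-similar of the three observables.
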