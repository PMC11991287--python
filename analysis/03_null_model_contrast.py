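#!/usr/bin/env python
"""Contrast the multiscale self-similarity against two surrogate ensembles:

* CP-WR — reshuffle weights per layer (geometry and topology kept): the
  cross-layer weight-distribution overlap survives, but the strength–degree
  exponent moves toward 1 and the weak-ties spectrum flattens;
* CR-GRW — reshuffle node angular positions before renormalizing: the
  cross-layer strength/degree overlap is destroyed.

Each surrogate is averaged over 10 realizations.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from grwnet.pipeline import PipelineConfig, run_nulls


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-nodes", type=int, default=4096)
    ap.add_argument("--reps", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results/null_models"))
    args = ap.parse_args()

    config = PipelineConfig(n_nodes=args.n_nodes, seed=args.seed,
                            n_realizations=args.reps)
    rep = run_nulls(config, out_dir=args.out_dir)
    orig = rep["original"]
    print(f"original flow:      KS(weights, l0-l3) = {orig['ks_weights_l0_lmax']:.3f}, "
          f"KS(strengths, l0-l3) = {orig['ks_strengths_l0_lmax']:.3f}, "
          f"eta_hat(l0) = {orig['eta_hat_l0']:.3f}")
    cp = rep["cp_wr"]
    print(f"CP-WR  ({rep['n_realizations']} reps): KS(weights) = "
          f"{cp['ks_weights_l0_lmax']['mean']:.3f} ± {cp['ks_weights_l0_lmax']['std']:.3f} "
          f"(unchanged), eta_hat = {cp['eta_hat_l0']['mean']:.3f} (→ 1)")
    cr = rep["cr_grw"]
    print(f"CR-GRW ({rep['n_realizations']} reps): KS(strengths) = "
          f"{cr['ks_strengths_l0_lmax']['mean']:.3f} ± {cr['ks_strengths_l0_lmax']['std']:.3f}, "
          f"KS(degrees) = {cr['ks_degrees_l0_lmax']['mean']:.3f} (overlap broken)")
    print(f"report written to {args.out_dir}")


if __name__ == "__main__":
    main()
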