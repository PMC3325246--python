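#!/usr/bin/env python
"""Exact per-matrix stability distribution for the full N=3, K=3 space.

Enumerates all 512 binary fully connected matrices against all 8 initial
states.  The distribution of per-matrix fixed-point fractions is
bimodal: most matrices either never reach a fixed point or always do —
stability is a property of the matrix, not of the initial state.
"""

import pandas as pd

from rtnstab import run_experiment

out = run_experiment({
    "recipe": "bimodality_enumeration",
    "seed": 0,
    "n_trials": 1,
    "params": {"n_genes": 3, "k": 3},
}, out_dir="results/03_bimodality")

hist = pd.read_csv(out / "per_matrix_histogram.tsv", sep="\t")
summary = pd.read_csv(out / "summary.tsv", sep="\t").iloc[0]
print(hist.to_string(index=False))
print(f"\nExact S = {summary.S_exact:.4f} over {summary.omega} "
      f"(matrix, state) pairs; {summary.n_never_stable} matrices are never "
      f"stable and {summary.n_always_stable} always stable — the two end "
      "bins dominate every interior stability value.")
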