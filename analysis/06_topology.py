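#!/usr/bin/env python
"""Topology: regular vs Poisson vs exponential-in/power-law-out degrees.

All three architectures at matched mean connectivity show the same
regime — cycles common, stability well below one — with second-order
shifts: degree heterogeneity leaves many genes with very few inputs,
which nudges stability upward at fixed mean K.
"""

import pandas as pd

from rtnstab import run_experiment

out = run_experiment({
    "recipe": "topology_comparison",
    "seed": 107,
    "n_trials": 5_000,
    "params": {"n_genes": 30, "k": 2},
}, out_dir="results/06_topology")

table = pd.read_csv(out / "stability.tsv", sep="\t")
print(table[["value", "S", "se"]].to_string(index=False))
spread = table.S.max() - table.S.min()
print(f"\nStability spread across topologies at N=30, K=2: {spread:.3f}; "
      "all remain in the cycle-dominated regime.")
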