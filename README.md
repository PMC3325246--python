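# rtnstab

Stability analysis of random threshold gene networks (the Wagner-style
gene network model). For researchers in systems biology and statistical
physics who use Boolean/threshold network ensembles to study gene
regulatory dynamics, robustness, and the assumptions behind
developmental-stability selection in evolutionary simulations.

## The model and the statistic

A network of N genes is an N×N signed interaction matrix W (w_ij: effect
of gene j on gene i; 0 = no interaction; diagonal = self-regulation).
Expression states update synchronously and deterministically:

    x(t+1) = σ(W · x(t))

with σ either the sign/step function (discrete states, off = −1 or 0)
or a sigmoid of steepness a (continuous states). Every discrete
trajectory ends in a fixed point or a limit cycle; the transient is the
developmental process, the attractor the phenotype.

Over Ω random (matrix, initial state) pairs with F fixed-point outcomes,

    S = F / Ω     (stability; 1 − S estimates the probability of cycling)

The package generates every ensemble variant studied in this model
family — regular, Poisson and exponential-in/power-law-out topologies;
binary ±1 or Gaussian weights; ±1 or 0/1 state maps; step or sigmoid
normalization; configurable σ(0) convention — iterates the dynamics to
the exact attractor (full state hashing: exact transient and period),
and measures S, per-matrix stability distributions, attractor period
distributions, transient scaling and phenotype discovery curves.

Headline behavior at desk scale: cycles dominate (S decreases
monotonically with both N and density; S < 0.1 already for dense
N = 16), per-matrix stability is bimodal (matrices are stable or
unstable almost independently of the initial state), sparse networks
are roughly twice as stable as dense ones, the 0/1 map is several-fold
more stable than the ±1 map, and even-length cycles are ≥ 2-fold
overrepresented under the ±1 map.

## Worked example

```python
import numpy as np
from rtnstab import DynamicsSpec, EnsembleSpec, estimate_stability, exact_stability

dyn = DynamicsSpec(map="pm1", norm="step")          # sign function, off = -1

# exact: every binary 3x3 matrix with 3 inputs/gene x every initial state
est, per_matrix = exact_stability(3, 3, dyn)
print(f"exact S = {est.s:.4f} over {est.omega} pairs")
print(f"never stable: {(per_matrix == 0).sum()}, always stable: {(per_matrix == 1).sum()}")

# Monte Carlo at a size where enumeration is impossible
ens = EnsembleSpec(n_genes=16, density=1.0)
mc = estimate_stability(ens, dyn, n_trials=10_000, rng=np.random.default_rng(1))
print(f"N=16 dense: S = {mc.s:.3f} +/- {mc.se:.3f}")
```

prints

```
exact S = 0.2656 over 4096 pairs
never stable: 300, always stable: 88
N=16 dense: S = 0.061 +/- 0.002
```

i.e. a quarter of small dense (matrix, state) pairs reach a fixed point,
the per-matrix distribution is bimodal (300 of 512 matrices never reach
one, 88 always do), and by N = 16 fixed points are a ~5% exception —
cycling is the rule.

The numbered scripts under `analysis/` run the full set of sweeps
(size, density, map, weights, steepness, topology, periods, transients,
discovery) and write TSV tables under `results/`. The same experiments
are available from a shell via configs:

```
rtnstab recipes                 # catalogue of the 11 experiment recipes
rtnstab run config.yaml         # run one, writing TSV + manifest + log
rtnstab enum --n 2 --k 2        # print an exact matrix-space enumeration
```

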