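"""The stability statistic S = F / Omega and its parameter sweeps.

Stability is the probability that a random (matrix, initial state) pair
reaches a fixed point: Omega pairs are drawn, Eq.-style dynamics are run
to the attractor on each, and S is the fraction F/Omega of fixed-point
outcomes.  1 - S estimates the probability of cycling.  Censored runs
(t_max exhausted) are counted as non-fixed-point by default and reported
separately; ``censoring="drop"`` excludes them from Omega instead.

For small N the statistic can be computed exactly by enumerating every
binary regular matrix and every initial state; the per-matrix fixed-point
fractions behind that average are exposed for distribution analyses
(stable vs unstable matrices).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import netgen
from .dynamics import DynamicsSpec, iterate_to_attractor
from .errors import GuardError, ParameterError
from .netgen import EnsembleSpec, WeightMatrix

MatrixFactory = Callable[[EnsembleSpec, np.random.Generator, int], WeightMatrix]


@dataclasses.dataclass
class StabilityEstimate:
    """Counts and estimate for S = F / Omega.

    ``omega`` is the number of trials entering the denominator, ``f`` the
    fixed-point count, ``cycles`` the cycle count and ``unresolved`` the
    censored count (F + cycles + unresolved = trials drawn).  ``se`` is
    the binomial (Wald) standard error, 0 for exact enumeration.
    """

    omega: int
    f: int
    cycles: int
    unresolved: int
    exact: bool = False
    provenance: dict | None = None

    @property
    def s(self) -> float:
        return self.f / self.omega if self.omega else float("nan")

    @property
    def se(self) -> float:
        if self.exact or self.omega == 0:
            return 0.0
        p = self.s
        return float(np.sqrt(p * (1.0 - p) / self.omega))

    def clopper_pearson(self, alpha: float = 0.05) -> tuple[float, float]:
        """Exact binomial interval — preferable to Wald when S is near 0 or 1."""
        from scipy.stats import beta

        f, n = self.f, self.omega
        lo = 0.0 if f == 0 else float(beta.ppf(alpha / 2, f, n - f + 1))
        hi = 1.0 if f == n else float(beta.ppf(1 - alpha / 2, f + 1, n - f))
        return lo, hi


@dataclasses.dataclass
class MatrixStability:
    """Per-matrix fixed-point fraction over initial states."""

    matrix_id: int
    trials: int
    fixed: int
    exact: bool

    @property
    def fraction(self) -> float:
        return self.fixed / self.trials


def estimate_stability(ens: EnsembleSpec, dyn: DynamicsSpec, n_trials: int,
                       rng: np.random.Generator,
                       matrix_factory: MatrixFactory | None = None,
                       censoring: str = "count_as_cycling") -> StabilityEstimate:
    """Monte Carlo S over fresh (matrix, initial state) pairs.

    One new matrix and one new uniform initial state per trial, matching
    the pair-sampling design under which a single state per matrix
    suffices (stability is a property of the matrix, and the bimodal
    per-matrix distribution makes the pair estimate consistent).

    ``matrix_factory`` overrides matrix generation (used for degenerate
    or fixed ensembles in tests and calibration).
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if censoring not in ("count_as_cycling", "drop"):
        raise ParameterError(f"unknown censoring mode {censoring!r}")
    factory = matrix_factory or netgen.generate_matrix
    f = cycles = unresolved = 0
    for i in range(n_trials):
        W = factory(ens, rng, i)
        x0 = netgen.random_initial_state(ens.n_genes, dyn.map, rng)
        res = iterate_to_attractor(W, x0, dyn)
        if res.outcome == "fixed_point":
            f += 1
        elif res.outcome == "cycle":
            cycles += 1
        else:
            unresolved += 1
    omega = n_trials if censoring == "count_as_cycling" else n_trials - unresolved
    return StabilityEstimate(
        omega=omega, f=f, cycles=cycles, unresolved=unresolved,
        provenance={"ensemble": ens.to_dict(), "dynamics": dyn.to_dict(),
                    "n_trials": n_trials, "censoring": censoring})


def matrix_fixed_fraction(W: WeightMatrix | np.ndarray, dyn: DynamicsSpec,
                          state_mode: str | tuple[str, int] = "all",
                          rng: np.random.Generator | None = None,
                          limit: int = netgen.ENUM_LIMIT) -> MatrixStability:
    """Fixed-point fraction of one matrix over its initial states."""
    n = W.n_genes if isinstance(W, WeightMatrix) else np.asarray(W).shape[0]
    if state_mode == "all":
        states: Iterable = netgen.enumerate_states(n, dyn.map, limit=limit)
        exact = True
        trials = 2 ** n
    else:
        mode, n_states = state_mode
        if mode != "sample":
            raise ParameterError(f"unknown state_mode {state_mode!r}")
        if rng is None:
            raise ParameterError("sampled state_mode needs an rng")
        states = (netgen.random_initial_state(n, dyn.map, rng)
                  for _ in range(n_states))
        exact = False
        trials = n_states
    fixed = sum(
        1 for x0 in states
        if iterate_to_attractor(W, x0, dyn).outcome == "fixed_point"
    )
    return MatrixStability(matrix_id=0, trials=trials, fixed=fixed, exact=exact)


def exact_stability(n: int, k: int, dyn: DynamicsSpec,
                    limit: int = netgen.ENUM_LIMIT
                    ) -> tuple[StabilityEstimate, np.ndarray]:
    """Exact S by full enumeration of binary regular matrices x states.

    Returns the estimate (se = 0) and the vector of per-matrix
    fixed-point fractions, in enumeration order.
    """
    n_states = 2 ** n
    total_matrices = netgen.count_binary_matrices(n, k)
    if total_matrices * n_states > limit:
        raise GuardError(
            f"full enumeration for N={n}, K={k} exceeds limit {limit}",
            total_matrices * n_states)
    f = cycles = 0
    fractions = np.empty(total_matrices)
    for m_idx, W in enumerate(netgen.enumerate_binary_matrices(n, k, limit=limit)):
        m_fixed = 0
        for x0 in netgen.enumerate_states(n, dyn.map, limit=limit):
            res = iterate_to_attractor(W, x0, dyn)
            if res.outcome == "fixed_point":
                m_fixed += 1
            else:
                cycles += 1
        f += m_fixed
        fractions[m_idx] = m_fixed / n_states
    omega = total_matrices * n_states
    est = StabilityEstimate(
        omega=omega, f=f, cycles=cycles, unresolved=0, exact=True,
        provenance={"n": n, "k": k, "dynamics": dyn.to_dict(), "mode": "exact"})
    return est, fractions


def matrix_stability_distribution(matrices: Iterable[WeightMatrix | np.ndarray],
                                  dyn: DynamicsSpec,
                                  state_mode: str | tuple[str, int] = "all",
                                  rng: np.random.Generator | None = None,
                                  n_bins: int = 20) -> dict:
    """Histogram of per-matrix stability (the stable/unstable dichotomy).

    Returns equal-width bin counts over [0, 1] plus separate tallies of
    exactly-0 (never stable) and exactly-1 (always stable) matrices.
    """
    fractions = []
    for i, W in enumerate(matrices):
        ms = matrix_fixed_fraction(W, dyn, state_mode=state_mode, rng=rng)
        ms.matrix_id = i
        fractions.append(ms.fraction)
    fr = np.asarray(fractions)
    counts, edges = np.histogram(fr, bins=n_bins, range=(0.0, 1.0))
    return {
        "fractions": fr,
        "bin_counts": counts,
        "bin_edges": edges,
        "n_exactly_zero": int((fr == 0.0).sum()),
        "n_exactly_one": int((fr == 1.0).sum()),
    }


_SWEEP_AXES = ("N", "c_or_K", "K", "c", "map", "weight_scheme", "steepness",
               "topology", "zero_convention")


def _apply_axis(axis: str, value, ens: EnsembleSpec, dyn: DynamicsSpec
                ) -> tuple[EnsembleSpec, DynamicsSpec]:
    if axis == "N":
        # a density-parameterized base spec keeps c fixed as N changes;
        # a K-parameterized one keeps K fixed
        return ens.replace(n_genes=int(value)), dyn
    if axis in ("K", "c_or_K"):
        return ens.replace(k=value, density=None), dyn
    if axis == "c":
        return ens.replace(density=float(value), k=None), dyn
    if axis == "map":
        return ens, dyn.replace(map=str(value))
    if axis == "weight_scheme":
        return ens.replace(weight_scheme=str(value)), dyn
    if axis == "steepness":
        return ens, dyn.replace(norm="sigmoid", steepness=float(value))
    if axis == "topology":
        return ens.replace(topology=str(value)), dyn
    if axis == "zero_convention":
        return ens, dyn.replace(zero_convention=str(value))
    raise ParameterError(f"unknown sweep axis {axis!r} (one of {_SWEEP_AXES})")


def sweep(axis: str, grid: Sequence, base_ens: EnsembleSpec,
          base_dyn: DynamicsSpec, n_trials: int, seed: int,
          matrix_factory: MatrixFactory | None = None,
          censoring: str = "count_as_cycling") -> pd.DataFrame:
    """One StabilityEstimate per grid point, from independent substreams.

    A single master seed spawns one child stream per grid point, so grid
    points are reproducible independently of each other.  Returns a tidy
    table (axis, value, S, se, omega, f, cycles, unresolved, seed).
    """
    if len(grid) == 0:
        raise ParameterError("sweep grid must be nonempty")
    children = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for value, child in zip(grid, children):
        ens, dyn = _apply_axis(axis, value, base_ens, base_dyn)
        rng = np.random.Generator(np.random.PCG64(child))
        est = estimate_stability(ens, dyn, n_trials, rng,
                                 matrix_factory=matrix_factory,
                                 censoring=censoring)
        rows.append({
            "axis": axis, "value": value, "S": est.s, "se": est.se,
            "omega": est.omega, "f": est.f, "cycles": est.cycles,
            "unresolved": est.unresolved, "seed": int(child.spawn_key[-1]),
        })
    return pd.DataFrame(rows)
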