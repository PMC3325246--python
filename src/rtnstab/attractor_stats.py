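"""Attractor-level statistics beyond the fixed-point/cycle dichotomy.

Period distributions (with the even/odd decomposition that exposes the
+/-1 map's antisymmetry-driven excess of even cycles), decay-law fits to
the period distribution, transient-time scaling across network sizes,
and coupon-collector-style discovery curves for fixed-point phenotypes.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from . import netgen
from .dynamics import DynamicsSpec, iterate_to_attractor
from .errors import FitError, ParameterError
from .netgen import EnsembleSpec
from .stability import MatrixFactory


@dataclasses.dataclass
class PeriodDistribution:
    """Counts of attractor periods over resolved runs."""

    map: str
    counts: dict[int, int]
    total: int
    unresolved: int

    def freq(self, period: int) -> float:
        return self.counts.get(period, 0) / self.total

    def even_odd_ratio(self, even_period: int) -> float:
        """f(L) / f(L+1) for even L — the even-cycle overrepresentation."""
        if even_period % 2:
            raise ParameterError("even_odd_ratio takes an even period")
        num = self.counts.get(even_period, 0)
        den = self.counts.get(even_period + 1, 0)
        return num / den if den else float("inf")

    @property
    def even_cycle_count(self) -> int:
        return sum(c for p, c in self.counts.items() if p >= 2 and p % 2 == 0)

    @property
    def odd_cycle_count(self) -> int:
        return sum(c for p, c in self.counts.items() if p >= 2 and p % 2 == 1)


def period_distribution(ens: EnsembleSpec, dyn: DynamicsSpec, n_trials: int,
                        rng: np.random.Generator,
                        matrix_factory: MatrixFactory | None = None
                        ) -> PeriodDistribution:
    """Tally attractor periods over fresh (matrix, initial state) pairs."""
    if not dyn.discrete:
        raise ParameterError("period_distribution requires discrete dynamics")
    factory = matrix_factory or netgen.generate_matrix
    counts: Counter[int] = Counter()
    unresolved = 0
    for i in range(n_trials):
        W = factory(ens, rng, i)
        x0 = netgen.random_initial_state(ens.n_genes, dyn.map, rng)
        res = iterate_to_attractor(W, x0, dyn)
        if res.outcome == "unresolved":
            unresolved += 1
        else:
            counts[res.period] += 1
    total = sum(counts.values())
    if total == 0:
        raise FitError("all runs unresolved; no periods observed")
    return PeriodDistribution(map=dyn.map, counts=dict(counts), total=total,
                              unresolved=unresolved)


def _lsq_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(slope), float(intercept), resid


def fit_decay(dist: PeriodDistribution, exclude_fixed: bool = True,
              split_parity: bool | None = None, min_count: int = 5) -> dict:
    """Least-squares decay fits to the cycle-length distribution.

    Fits log-frequency against period (exponential law) and against
    log-period (power law) and reports residual sums for comparison.
    Fixed points (period 1) are excluded by default — these are
    cycle-length distributions.  For the +/-1 map, even and odd periods
    are fitted separately by default because the antisymmetry of that
    map makes the even branch sit well above the odd one.  Periods with
    fewer than ``min_count`` observations are dropped to keep the
    unweighted log-space fit from being dominated by tail noise.
    """
    if split_parity is None:
        split_parity = dist.map == "pm1"
    items = sorted(
        (p, c) for p, c in dist.counts.items()
        if c >= min_count and not (exclude_fixed and p == 1)
    )
    branches = {}
    if split_parity:
        branches["even"] = [(p, c) for p, c in items if p % 2 == 0]
        branches["odd"] = [(p, c) for p, c in items if p % 2 == 1]
    else:
        branches["all"] = items
    out = {}
    for name, pts in branches.items():
        if len(pts) < 4:
            raise FitError(
                f"{name} branch has {len(pts)} supported periods; need >= 4")
        periods = np.array([p for p, _ in pts], dtype=float)
        logf = np.log(np.array([c for _, c in pts], dtype=float) / dist.total)
        slope_e, icpt_e, resid_e = _lsq_line(periods, logf)
        slope_p, icpt_p, resid_p = _lsq_line(np.log(periods), logf)
        out[name] = {
            "exponential_rate": -slope_e,
            "exponential_intercept": icpt_e,
            "exponential_resid": resid_e,
            "powerlaw_slope": -slope_p,
            "powerlaw_intercept": icpt_p,
            "powerlaw_resid": resid_p,
            "n_points": len(pts),
        }
    return out


def transient_summary(ens_grid: Sequence[EnsembleSpec], dyn: DynamicsSpec,
                      n_trials: int, seed: int,
                      matrix_factory: MatrixFactory | None = None
                      ) -> pd.DataFrame:
    """Mean transient to a fixed point, per ensemble (cycles excluded).

    Ensembles where no fixed point was observed get NaN means (a missing
    cell, not a failure).  This is the quantity used to calibrate t_max
    cutoffs for large or dense networks.
    """
    factory = matrix_factory or netgen.generate_matrix
    children = np.random.SeedSequence(seed).spawn(len(ens_grid))
    rows = []
    for ens, child in zip(ens_grid, children):
        rng = np.random.Generator(np.random.PCG64(child))
        transients = []
        unresolved = 0
        for i in range(n_trials):
            W = factory(ens, rng, i)
            x0 = netgen.random_initial_state(ens.n_genes, dyn.map, rng)
            res = iterate_to_attractor(W, x0, dyn)
            if res.outcome == "fixed_point":
                transients.append(res.transient)
            elif res.outcome == "unresolved":
                unresolved += 1
        tr = np.asarray(transients, dtype=float)
        rows.append({
            "n_genes": ens.n_genes,
            "k": ens.connectivity,
            "n_fixed": len(transients),
            "mean_transient": float(tr.mean()) if len(tr) else float("nan"),
            "sd_transient": float(tr.std(ddof=1)) if len(tr) > 1 else float("nan"),
            "unresolved": unresolved,
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class DiscoveryCurve:
    """Samples-to-discovery trace for distinct fixed-point phenotypes."""

    discovery_samples: list[int]      # sample index at each new phenotype
    n_discovered: int
    n_samples: int
    censored: bool                    # stopped at max_samples before target


def discovery_curve(ens: EnsembleSpec, dyn: DynamicsSpec,
                    rng: np.random.Generator,
                    target_count: int | None = None,
                    max_samples: int = 10_000,
                    matrix_factory: MatrixFactory | None = None
                    ) -> DiscoveryCurve:
    """Sequentially sample pairs, tracking distinct fixed-point states.

    A phenotype is a distinct fixed-point state vector, pooled across the
    sampled matrices of the ensemble.  Stops when ``target_count``
    distinct phenotypes have been seen or at ``max_samples`` (censoring
    is an outcome, recorded on the result).
    """
    if not dyn.discrete:
        raise ParameterError("discovery_curve requires discrete dynamics")
    factory = matrix_factory or netgen.generate_matrix
    seen: set[bytes] = set()
    discoveries: list[int] = []
    for i in range(1, max_samples + 1):
        W = factory(ens, rng, i - 1)
        x0 = netgen.random_initial_state(ens.n_genes, dyn.map, rng)
        res = iterate_to_attractor(W, x0, dyn)
        if res.outcome == "fixed_point":
            key = res.attractor_states[0].tobytes()
            if key not in seen:
                seen.add(key)
                discoveries.append(i)
                if target_count is not None and len(seen) >= target_count:
                    return DiscoveryCurve(discoveries, len(seen), i, False)
    censored = target_count is not None and len(seen) < target_count
    return DiscoveryCurve(discoveries, len(seen), max_samples, censored)
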