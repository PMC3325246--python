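"""Random-network and initial-state generators.

The model operates on an N x N signed interaction matrix W whose entry
w_ij is the regulatory effect of gene j's product on gene i (0 means no
interaction; the diagonal is self-regulation and the matrix is generally
not symmetric).  This module draws W from the ensembles studied in the
stability analyses:

* ``regular`` — every gene has exactly K inputs chosen uniformly;
* ``poisson`` — in-degrees are Poisson with mean K, truncated to [0, N];
* ``bio_exp_in_pow_out`` — exponential in-degree and power-law out-degree
  distributions, both with mean K, a parametric stand-in for the degree
  statistics reported for transcriptional networks.

Weights are either binary (+1/-1 equiprobable) or standard-normal reals.
Initial expression states are drawn uniformly over the 2^N discrete
corners of the state space in either the +/-1 or the 0/1 convention.
Exact enumerators over the binary matrix space and the state space are
provided for small N, guarded by explicit size bounds.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from math import comb
from typing import Iterator

import numpy as np

from .errors import GenerationError, GuardError, ParameterError

TOPOLOGIES = ("regular", "poisson", "bio_exp_in_pow_out")
WEIGHT_SCHEMES = ("binary_pm1", "real_gaussian")
STATE_MAPS = ("pm1", "zero_one")

#: default cap on exact enumeration sizes
ENUM_LIMIT = 2_000_000


@dataclasses.dataclass(frozen=True)
class EnsembleSpec:
    """Full description of a random-network ensemble.

    Exactly one of ``k`` (mean in-degree) and ``density`` (fraction c of
    nonzero entries) may be given; the other is derived through c = K/N.

    Parameters
    ----------
    n_genes
        Network size N.
    k
        Connectivity K: inputs per gene (exact for the regular topology,
        the distribution mean otherwise).
    density
        Fraction of nonzero matrix entries, c = K/N.
    topology
        One of ``regular``, ``poisson``, ``bio_exp_in_pow_out``.
    weight_scheme
        ``binary_pm1`` (+/-1 equiprobable) or ``real_gaussian``.
    allow_self_loops
        Whether diagonal entries (self-regulation) may be drawn.
    seed
        Optional ensemble-level seed recorded for provenance.
    """

    n_genes: int
    k: float | None = None
    density: float | None = None
    topology: str = "regular"
    weight_scheme: str = "binary_pm1"
    allow_self_loops: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.topology not in TOPOLOGIES:
            raise ParameterError(f"unknown topology {self.topology!r}")
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ParameterError(f"unknown weight_scheme {self.weight_scheme!r}")
        if self.k is None and self.density is None:
            raise ParameterError("one of k or density must be given")
        if self.k is not None and self.density is not None:
            if abs(self.k - self.density * self.n_genes) > 1e-9:
                raise ParameterError(
                    f"k={self.k} and density={self.density} conflict (c = K/N)"
                )
        if self.k is not None and not 0 < self.k <= self.n_genes:
            raise ParameterError(
                f"K={self.k} outside [1, N={self.n_genes}] (field 'k')")
        c = self.connectivity / self.n_genes
        if not 0 < c <= 1:
            raise ParameterError(f"density c={c} outside (0, 1] (field 'k'/'density')")
        if self.topology == "regular":
            kk = self.connectivity
            if abs(kk - round(kk)) > 1e-9:
                raise ParameterError(f"regular topology needs integer K, got {kk}")
            if not 1 <= round(kk) <= self.n_genes:
                raise ParameterError(f"K={kk} outside [1, N={self.n_genes}]")
            if not self.allow_self_loops and round(kk) > self.n_genes - 1:
                raise ParameterError("K > N-1 with self-loops disallowed")

    @property
    def connectivity(self) -> float:
        """Mean in-degree K (derived from density if K was not given)."""
        if self.k is not None:
            return float(self.k)
        return float(self.density * self.n_genes)

    @property
    def c(self) -> float:
        """Network density c = K/N."""
        return self.connectivity / self.n_genes

    def to_dict(self) -> dict:
        """Flat key-value form, round-trips through YAML/JSON."""
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSpec":
        return cls(**d)

    def replace(self, **kw) -> "EnsembleSpec":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class WeightMatrix:
    """An interaction matrix plus generation provenance.

    ``tie_signs`` is a per-gene +/-1 vector drawn at creation time; it is
    consulted only when the dynamics run under the ``quenched_random``
    zero-input convention, keeping the update deterministic.
    """

    entries: np.ndarray
    scheme: str = "binary_pm1"
    spec: EnsembleSpec | None = None
    draw_index: int = 0
    tie_signs: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.entries.shape[0]

    def in_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.entries, axis=1)

    def out_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.entries, axis=0)

    def to_edge_list(self):
        """Edge list as a (source, target, weight) DataFrame (w_ij: j -> i)."""
        import pandas as pd

        tgt, src = np.nonzero(self.entries)
        return pd.DataFrame(
            {"source": src, "target": tgt, "weight": self.entries[tgt, src]}
        )

    def to_dense_text(self) -> str:
        """Dense tab-separated matrix text, one row per line."""
        return "\n".join(
            "\t".join(format(v, "g") for v in row) for row in self.entries
        )


@dataclasses.dataclass
class StateVector:
    """A gene-expression state in the +/-1 or 0/1 convention."""

    values: np.ndarray
    map: str = "pm1"
    discrete: bool = True

    def __post_init__(self) -> None:
        if self.map not in STATE_MAPS:
            raise ParameterError(f"unknown state map {self.map!r}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.discrete:
            legal = {-1.0, 1.0} if self.map == "pm1" else {0.0, 1.0}
            if not set(np.unique(v)) <= legal:
                raise ParameterError(f"discrete {self.map} state has values {np.unique(v)}")

    def __len__(self) -> int:
        return len(self.values)


def _draw_weights(scheme: str, size: int, rng: np.random.Generator) -> np.ndarray:
    if scheme == "binary_pm1":
        return rng.integers(0, 2, size=size) * 2.0 - 1.0
    return rng.standard_normal(size)


def _as_matrix(spec: EnsembleSpec, W: np.ndarray, rng: np.random.Generator,
               draw_index: int = 0) -> WeightMatrix:
    tie = rng.integers(0, 2, size=spec.n_genes) * 2 - 1
    return WeightMatrix(entries=W, scheme=spec.weight_scheme, spec=spec,
                        draw_index=draw_index, tie_signs=tie)


def generate_regular(spec: EnsembleSpec, rng: np.random.Generator,
                     draw_index: int = 0) -> WeightMatrix:
    """Draw a matrix in which every gene has exactly K inputs.

    Input positions are uniform without replacement over the N columns
    (excluding the diagonal if self-loops are disallowed); nonzero values
    follow the weight scheme.
    """
    if spec.topology != "regular":
        raise ParameterError(f"spec topology is {spec.topology!r}, not regular")
    n, k = spec.n_genes, int(round(spec.connectivity))
    keys = rng.random((n, n))
    if not spec.allow_self_loops:
        np.fill_diagonal(keys, np.inf)
    if k < n:
        cols = np.argpartition(keys, k - 1, axis=1)[:, :k]
    else:
        cols = np.tile(np.arange(n), (n, 1))
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, cols.ravel()] = _draw_weights(spec.weight_scheme, n * k, rng)
    return _as_matrix(spec, W, rng, draw_index)


def _truncated_poisson(mean: float, n_max: int, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Poisson(mean) conditioned on values in [0, n_max], by rejection."""
    out = rng.poisson(mean, size=size)
    bad = out > n_max
    while bad.any():
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
        bad = out > n_max
    return out


def truncated_poisson_mean(mean: float, n_max: int) -> float:
    """Exact mean of Poisson(mean) truncated to [0, n_max]."""
    ks = np.arange(n_max + 1)
    logp = ks * math.log(mean) - mean - np.array([math.lgamma(k + 1) for k in ks])
    p = np.exp(logp)
    p /= p.sum()
    return float((ks * p).sum())


def _fill_rows(spec: EnsembleSpec, in_degrees: np.ndarray,
               rng: np.random.Generator, col_weights: np.ndarray | None = None
               ) -> np.ndarray:
    """Place each row's inputs; columns uniform or weighted, no repeats."""
    n = spec.n_genes
    W = np.zeros((n, n))
    base = np.ones(n) if col_weights is None else np.asarray(col_weights, float)
    for i in range(n):
        d = int(in_degrees[i])
        if d == 0:
            continue
        w = base.copy()
        if not spec.allow_self_loops:
            w[i] = 0.0
        avail = int(np.count_nonzero(w))
        if d > avail:
            d = avail
        # Efraimidis-Spirakis keys: weighted sampling without replacement
        with np.errstate(divide="ignore"):
            keys = np.where(w > 0, rng.random(n) ** (1.0 / np.where(w > 0, w, 1.0)), -1.0)
        cols = np.argpartition(-keys, d - 1)[:d]
        W[i, cols] = _draw_weights(spec.weight_scheme, d, rng)
    return W


def generate_poisson(spec: EnsembleSpec, rng: np.random.Generator,
                     draw_index: int = 0) -> WeightMatrix:
    """Draw a matrix with Poisson(K) in-degrees truncated to [0, N].

    Genes with in-degree 0 get an all-zero row; their update is then
    governed entirely by the dynamics' zero-input convention.
    """
    if spec.topology != "poisson":
        raise ParameterError(f"spec topology is {spec.topology!r}, not poisson")
    n = spec.n_genes
    n_max = n if spec.allow_self_loops else n - 1
    deg = _truncated_poisson(spec.connectivity, n_max, n, rng)
    W = _fill_rows(spec, deg, rng)
    return _as_matrix(spec, W, rng, draw_index)


def solve_exponential_rate(mean: float, n_max: int) -> float:
    """Rate of a discretized exponential on {0..n_max} with the given mean."""
    ks = np.arange(n_max + 1)

    def m(rate: float) -> float:
        e = -rate * ks.astype(float)
        p = np.exp(e - e.max())        # shift exponents to avoid overflow
        return float((ks * p).sum() / p.sum())

    # negative rates cover degenerate tiny-N cases where the requested mean
    # exceeds n_max/2 (a decaying exponential cannot reach it)
    lo, hi = -50.0, 50.0
    if not m(hi) <= mean <= m(lo):
        raise ParameterError(f"no exponential rate gives mean {mean} on [0,{n_max}]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if m(mid) > mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_powerlaw_exponent(mean: float, n_max: int,
                            bracket: tuple[float, float] = (1.5, 4.0)) -> float:
    """Exponent gamma of P(d) ~ d^-gamma on {1..n_max} matching the mean.

    Solved by bisection on the bracket; the mean is decreasing in gamma.
    """
    ks = np.arange(1, n_max + 1, dtype=float)

    def m(g: float) -> float:
        p = ks ** (-g)
        return float((ks * p).sum() / p.sum())

    lo, hi = bracket
    # degenerate tiny supports (n_max of a few) cannot reach every mean;
    # clamp to the nearest bracket edge there
    if mean <= m(hi):
        return hi
    if mean >= m(lo):
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if m(mid) > mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_discrete_exponential(mean: float, n_max: int, size: int,
                                rng: np.random.Generator) -> np.ndarray:
    rate = solve_exponential_rate(mean, n_max)
    ks = np.arange(n_max + 1)
    e = -rate * ks.astype(float)
    p = np.exp(e - e.max())
    return rng.choice(ks, size=size, p=p / p.sum())


def sample_discrete_powerlaw(mean: float, n_max: int, size: int,
                             rng: np.random.Generator) -> np.ndarray:
    g = solve_powerlaw_exponent(mean, n_max)
    ks = np.arange(1, n_max + 1, dtype=float)
    p = ks ** (-g)
    return rng.choice(np.arange(1, n_max + 1), size=size, p=p / p.sum())


def generate_biological(spec: EnsembleSpec, rng: np.random.Generator,
                        draw_index: int = 0) -> WeightMatrix:
    """Draw a matrix with exponential in- and power-law out-degrees.

    In-degrees come from a discretized exponential with mean K (truncated
    to [0, N]); out-degree stub counts come from a discrete power law on
    {1..N} whose exponent is solved so the mean equals K.  Each row's
    sources are then drawn without replacement with probability
    proportional to the stub counts, so in-degrees are exact and
    out-degrees follow the heavy-tailed law in expectation (duplicate
    stub pairings collapse and are re-drawn within the row).
    """
    if spec.topology != "bio_exp_in_pow_out":
        raise ParameterError(f"spec topology is {spec.topology!r}, not biological")
    n = spec.n_genes
    n_max = n if spec.allow_self_loops else n - 1
    for _attempt in range(100):
        in_deg = sample_discrete_exponential(spec.connectivity, n_max, n, rng)
        out_stubs = sample_discrete_powerlaw(spec.connectivity, n, n, rng)
        if out_stubs.sum() > 0:
            W = _fill_rows(spec, in_deg, rng, col_weights=out_stubs.astype(float))
            return _as_matrix(spec, W, rng, draw_index)
    raise GenerationError(f"stub matching failed for {spec}")


_GENERATORS = {
    "regular": generate_regular,
    "poisson": generate_poisson,
    "bio_exp_in_pow_out": generate_biological,
}


def generate_matrix(spec: EnsembleSpec, rng: np.random.Generator,
                    draw_index: int = 0) -> WeightMatrix:
    """Dispatch to the generator for ``spec.topology``."""
    return _GENERATORS[spec.topology](spec, rng, draw_index)


def count_binary_matrices(n: int, k: int) -> int:
    """Number of N x N matrices with exactly K nonzero +/-1 entries per row."""
    return (comb(n, k) * 2 ** k) ** n


def enumerate_binary_matrices(n: int, k: int, limit: int = ENUM_LIMIT
                              ) -> Iterator[WeightMatrix]:
    """Yield every binary regular matrix exactly once.

    The space has (C(N,K) * 2^K)^N elements; requests beyond ``limit``
    are refused with the computed count.
    """
    if not 1 <= k <= n:
        raise ParameterError(f"K={k} outside [1, N={n}]")
    total = count_binary_matrices(n, k)
    if total > limit:
        raise GuardError(f"binary matrix space for N={n}, K={k} exceeds limit {limit}", total)
    positions = list(itertools.combinations(range(n), k))
    signs = list(itertools.product((-1.0, 1.0), repeat=k))
    row_choices = [(pos, sg) for pos in positions for sg in signs]
    for rows in itertools.product(row_choices, repeat=n):
        W = np.zeros((n, n))
        for i, (pos, sg) in enumerate(rows):
            W[i, list(pos)] = sg
        yield WeightMatrix(entries=W, scheme="binary_pm1")


def random_initial_state(n: int, map: str, rng: np.random.Generator) -> StateVector:
    """Uniform draw over the 2^N discrete states of the given map."""
    if map not in STATE_MAPS:
        raise ParameterError(f"unknown state map {map!r}")
    bits = rng.integers(0, 2, size=n).astype(float)
    vals = bits * 2 - 1 if map == "pm1" else bits
    return StateVector(values=vals, map=map)


def enumerate_states(n: int, map: str, limit: int = ENUM_LIMIT) -> Iterator[StateVector]:
    """Yield all 2^N discrete states exactly once (guarded)."""
    if map not in STATE_MAPS:
        raise ParameterError(f"unknown state map {map!r}")
    total = 2 ** n
    if total > limit:
        raise GuardError(f"state space for N={n} exceeds limit {limit}", total)
    off = -1.0 if map == "pm1" else 0.0
    for bits in itertools.product((off, 1.0), repeat=n):
        yield StateVector(values=np.array(bits), map=map)
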