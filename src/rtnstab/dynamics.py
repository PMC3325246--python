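"""Synchronous threshold dynamics and attractor detection.

The update rule is x(t+1) = sigma(W x(t)), applied to all genes
simultaneously.  sigma is either the step (sign/threshold) function,
giving discrete Boolean-type dynamics, or a sigmoid of steepness ``a``,
giving continuous dynamics on the interior of the state cube; the
sigmoid converges to the step function as a -> infinity.  Because the
discrete state space is finite and the dynamics deterministic, every
discrete trajectory ends in a fixed point or a limit cycle; the discrete
detector here is exact (full state hashing reports both transient and
period).  Continuous trajectories are classified within tolerance.

Zero net input (h_i = 0) has no canonical image under the sign function;
the convention is configurable: ``minus`` (off state, the default),
``plus`` (on state), ``quenched_random`` (a per-gene tie-break sign
fixed at matrix creation, so the dynamics stay deterministic), or
``keep_previous`` (the gene holds its state).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ParameterError
from .netgen import StateVector, WeightMatrix

ZERO_CONVENTIONS = ("minus", "plus", "quenched_random", "keep_previous")
NORM_KINDS = ("step", "sigmoid")


@dataclasses.dataclass(frozen=True)
class RunLimits:
    """Iteration caps and continuous-case tolerances.

    ``t_max=None`` selects the default policy
    ``min(2^N, max(10^4, 100 N))``; discrete runs are additionally
    bounded by 2^N + 1 steps, past which a revisit is guaranteed.
    """

    t_max: int | None = None
    eps: float = 1e-6
    window: int = 10

    def __post_init__(self) -> None:
        if self.t_max is not None and self.t_max < 1:
            raise ParameterError("t_max must be >= 1")
        if self.eps <= 0 or self.window < 1:
            raise ParameterError("eps must be > 0 and window >= 1")

    def resolve_t_max(self, n: int, discrete: bool) -> int:
        # the 2^N cap is a pigeonhole bound, meaningful only for discrete
        # states; continuous runs need at least `window` quiet steps
        if self.t_max is not None:
            t = self.t_max
        else:
            t = max(10_000, 100 * n)
            if discrete and n < 60:
                t = min(t, 2 ** n)
        if discrete and n < 60:
            t = min(t, 2 ** n + 1)
        return t


@dataclasses.dataclass(frozen=True)
class DynamicsSpec:
    """State map, normalization and zero-input convention for Eq.-style updates."""

    map: str = "pm1"
    norm: str = "step"
    steepness: float = 10.0
    zero_convention: str = "minus"
    limits: RunLimits = dataclasses.field(default_factory=RunLimits)

    def __post_init__(self) -> None:
        if self.map not in ("pm1", "zero_one"):
            raise ParameterError(f"unknown map {self.map!r}")
        if self.norm not in NORM_KINDS:
            raise ParameterError(f"unknown norm {self.norm!r}")
        if self.zero_convention not in ZERO_CONVENTIONS:
            raise ParameterError(f"unknown zero_convention {self.zero_convention!r}")
        if self.norm == "sigmoid" and self.steepness <= 0:
            raise ParameterError("sigmoid steepness must be > 0")

    @property
    def discrete(self) -> bool:
        return self.norm == "step"

    @property
    def on_off(self) -> tuple[float, float]:
        return (1.0, -1.0) if self.map == "pm1" else (1.0, 0.0)

    def replace(self, **kw) -> "DynamicsSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["limits"] = dataclasses.asdict(self.limits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicsSpec":
        d = dict(d)
        if "limits" in d and isinstance(d["limits"], dict):
            d["limits"] = RunLimits(**d["limits"])
        return cls(**d)


@dataclasses.dataclass
class TrajectoryResult:
    """Outcome of iterating one (matrix, initial state) pair to its attractor."""

    outcome: str                      # fixed_point | cycle | unresolved
    period: int | None
    transient: int | None
    steps_run: int
    attractor_states: list[np.ndarray] | None = None

    @property
    def is_fixed_point(self) -> bool:
        return self.outcome == "fixed_point"


def _coerce_entries(W: WeightMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(W, WeightMatrix):
        return np.asarray(W.entries, dtype=float), W.tie_signs
    return np.asarray(W, dtype=float), None


def _coerce_state(x) -> np.ndarray:
    if isinstance(x, StateVector):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _sigmoid(h: np.ndarray, a: float, map: str) -> np.ndarray:
    if map == "pm1":
        return np.tanh(0.5 * a * h)          # == 2/(1+exp(-a h)) - 1
    from scipy.special import expit          # overflow-safe logistic

    return expit(a * h)


def _threshold(h: np.ndarray, x: np.ndarray, spec: DynamicsSpec,
               tie_signs: np.ndarray | None) -> np.ndarray:
    on, off = spec.on_off
    out = np.where(h > 0, on, off)
    zero = h == 0
    if zero.any():
        zc = spec.zero_convention
        if zc == "plus":
            out[zero] = on
        elif zc == "keep_previous":
            out[zero] = x[zero]
        elif zc == "quenched_random":
            if tie_signs is None:
                raise ParameterError(
                    "quenched_random convention needs a WeightMatrix with tie_signs"
                )
            out[zero] = np.where(tie_signs[zero] > 0, on, off)
        # "minus": off already in place
    return out


def step(W: WeightMatrix | np.ndarray, x, spec: DynamicsSpec) -> np.ndarray:
    """One synchronous update: sigma(W x) componentwise.

    Accepts a ``WeightMatrix`` or a raw array, and a ``StateVector`` or a
    raw array; returns a raw array in the same state map.
    """
    entries, tie = _coerce_entries(W)
    xv = _coerce_state(x)
    if entries.shape != (xv.size, xv.size):
        raise ParameterError(
            f"dimension mismatch: W is {entries.shape}, x has {xv.size} genes"
        )
    h = entries @ xv
    if spec.norm == "sigmoid":
        return _sigmoid(h, spec.steepness, spec.map)
    return _threshold(h, xv, spec, tie)


def _run_discrete(entries: np.ndarray, x0: np.ndarray, spec: DynamicsSpec,
                  tie: np.ndarray | None, t_max: int,
                  keep_states: bool) -> TrajectoryResult:
    on, off = spec.on_off
    zc = spec.zero_convention
    seen: dict[bytes, int] = {}
    history: list[np.ndarray] = []
    x = x0
    key = x.tobytes()
    t = 0
    while t <= t_max:
        t0 = seen.get(key)
        if t0 is not None:
            period = t - t0
            outcome = "fixed_point" if period == 1 else "cycle"
            attractor = None
            if keep_states or period == 1:
                attractor = [history[i].copy() for i in range(t0, t)]
            return TrajectoryResult(outcome=outcome, period=period,
                                    transient=t0, steps_run=t,
                                    attractor_states=attractor)
        seen[key] = t
        history.append(x)
        h = entries @ x
        nxt = np.where(h > 0, on, off)
        zero = h == 0
        if zero.any():
            if zc == "plus":
                nxt[zero] = on
            elif zc == "keep_previous":
                nxt[zero] = x[zero]
            elif zc == "quenched_random":
                if tie is None:
                    raise ParameterError(
                        "quenched_random convention needs a WeightMatrix with tie_signs"
                    )
                nxt[zero] = np.where(tie[zero] > 0, on, off)
        x = nxt
        key = x.tobytes()
        t += 1
    return TrajectoryResult(outcome="unresolved", period=None, transient=None,
                            steps_run=t_max)


def _run_continuous(entries: np.ndarray, x0: np.ndarray, spec: DynamicsSpec,
                    t_max: int, keep_states: bool) -> TrajectoryResult:
    """Tolerance-based classification for sigmoid dynamics.

    Fixed point: max-norm step change below eps for ``window`` consecutive
    steps.  Cycle: the current state returns within eps of a checkpoint
    stored at power-of-two times (Brent-style, memory O(1)); transient is
    then reported as the checkpoint time (an upper bound).
    """
    eps, window = spec.limits.eps, spec.limits.window
    a, m = spec.steepness, spec.map
    x = x0
    quiet = 0
    checkpoint = x.copy()
    check_t = 0
    next_power = 1
    for t in range(1, t_max + 1):
        nxt = _sigmoid(entries @ x, a, m)
        if np.max(np.abs(nxt - x)) < eps:
            quiet += 1
            if quiet >= window:
                return TrajectoryResult(
                    outcome="fixed_point", period=1, transient=max(0, t - window),
                    steps_run=t, attractor_states=[nxt.copy()])
        else:
            quiet = 0
        x = nxt
        # cycle check only while the trajectory is actually moving,
        # else a settled fixed point matches checkpoints at distance > 1
        if quiet == 0 and t > check_t and np.max(np.abs(x - checkpoint)) < eps:
            period = t - check_t
            if period > 1:
                return TrajectoryResult(
                    outcome="cycle", period=period, transient=check_t,
                    steps_run=t,
                    attractor_states=[x.copy()] if keep_states else None)
        if t == next_power:
            checkpoint = x.copy()
            check_t = t
            next_power *= 2
    return TrajectoryResult(outcome="unresolved", period=None, transient=None,
                            steps_run=t_max)


def iterate_to_attractor(W: WeightMatrix | np.ndarray, x0,
                         spec: DynamicsSpec,
                         keep_states: bool = False) -> TrajectoryResult:
    """Iterate the synchronous dynamics from x0 until the attractor is found.

    Discrete (step) dynamics hash every visited state, so the reported
    transient and period are exact whenever t_max >= transient + period —
    guaranteed by the 2^N + 1 bound.  Exhausting t_max yields
    ``outcome="unresolved"``, never an exception.  Fixed-point states are
    always retained in ``attractor_states``; cycle states only when
    ``keep_states`` is set.
    """
    entries, tie = _coerce_entries(W)
    x = _coerce_state(x0)
    n = x.size
    if entries.shape != (n, n):
        raise ParameterError(f"dimension mismatch: W is {entries.shape}, x has {n} genes")
    t_max = spec.limits.resolve_t_max(n, spec.discrete)
    if spec.discrete:
        return _run_discrete(entries, x, spec, tie, t_max, keep_states)
    return _run_continuous(entries, x, spec, t_max, keep_states)


def brent_cycle_length(W: WeightMatrix | np.ndarray, x0, spec: DynamicsSpec,
                       t_max: int | None = None) -> int | None:
    """Low-memory (O(1)) period finder for discrete runs (Brent's algorithm).

    Returns the attractor period, or None if t_max is exhausted first.
    Unlike :func:`iterate_to_attractor` it does not report the transient;
    it exists for very long runs where the hash table would be costly.
    """
    if not spec.discrete:
        raise ParameterError("brent_cycle_length applies to discrete dynamics")
    entries, tie = _coerce_entries(W)
    x = _coerce_state(x0)
    cap = t_max if t_max is not None else spec.limits.resolve_t_max(x.size, True)

    def f(v: np.ndarray) -> np.ndarray:
        return _threshold(entries @ v, v, spec, tie)

    power = lam = 1
    tortoise, hare = x, f(x)
    steps = 1
    while not np.array_equal(tortoise, hare):
        if steps >= cap:
            return None
        if power == lam:
            tortoise = hare
            power *= 2
            lam = 0
        hare = f(hare)
        steps += 1
        lam += 1
    return lam


def trajectory_states(W, x0, spec: DynamicsSpec, n_steps: int) -> np.ndarray:
    """The first ``n_steps + 1`` states (including x0) as a (T+1, N) array."""
    entries, tie = _coerce_entries(W)
    x = _coerce_state(x0)
    out = np.empty((n_steps + 1, x.size))
    out[0] = x
    for t in range(1, n_steps + 1):
        if spec.norm == "sigmoid":
            x = _sigmoid(entries @ x, spec.steepness, spec.map)
        else:
            x = _threshold(entries @ x, x, spec, tie)
        out[t] = x
    return out


def sigmoid_matches_sign(W: WeightMatrix | np.ndarray, x0, a: float,
                         horizon: int) -> bool:
    """Whether the steep-sigmoid trajectory shadows the sign trajectory.

    Requires binary +/-1 weights under the +/-1 map with odd in-degree K
    for every gene, so net inputs are odd integers and never zero (a zero
    input would make the comparison depend on the tie-break convention).
    True iff sign(sigmoid trajectory) equals the step trajectory
    componentwise for ``horizon`` steps.
    """
    entries, _ = _coerce_entries(W)
    vals = np.unique(entries[entries != 0])
    if not set(vals) <= {-1.0, 1.0}:
        raise ParameterError("sigmoid_matches_sign requires binary +/-1 weights")
    degs = np.count_nonzero(entries, axis=1)
    if np.any(degs % 2 == 0):
        raise ParameterError(
            "sigmoid_matches_sign requires odd in-degree K (even K admits "
            "zero net inputs, making the comparison ill-defined)"
        )
    step_spec = DynamicsSpec(map="pm1", norm="step")
    sig_spec = DynamicsSpec(map="pm1", norm="sigmoid", steepness=a)
    xs = _coerce_state(x0)
    xc = xs.copy()
    for _ in range(horizon):
        xs = _threshold(entries @ xs, xs, step_spec, None)
        xc = _sigmoid(entries @ xc, a, "pm1")
        if np.any(np.sign(xc) != xs):
            return False
    return True


def trajectory_to_frame(states: np.ndarray):
    """Long-form (time, gene, value) DataFrame for a (T, N) state array."""
    import pandas as pd

    t, n = states.shape
    return pd.DataFrame({
        "time": np.repeat(np.arange(t), n),
        "gene": np.tile(np.arange(n), t),
        "value": states.ravel(),
    })
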