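# Methods

## The model

A gene network of N genes is an N×N signed matrix W; entry w_ij is the
regulatory effect of gene j's product on gene i (0 = no interaction,
diagonal = self-regulation, W generally not symmetric). The expression
state x(t) evolves by the synchronous, deterministic update

    x(t+1) = σ(W · x(t)),

where σ is applied componentwise. The transient from an initial state to
the attractor is read as a developmental process and the attractor as
the phenotype. With discrete states the state space is finite, so every
trajectory ends in a fixed point (period 1) or a limit cycle (period ≥ 2).

**Stability** is S = F/Ω: of Ω independent (matrix, initial state)
pairs, the fraction F/Ω whose attractor is a fixed point. 1 − S estimates
the probability of cycling. One fresh matrix and one fresh uniform
initial state are drawn per trial; because per-matrix stability is
strongly bimodal (see below), this pair design is an efficient and
consistent estimator and multi-state sampling per matrix is needed only
for distribution analyses.

## Normalization functions and the σ(0) convention

* `step`: the sign/threshold function. Codomain {−1, +1} under the ±1
  map, {0, 1} under the 0/1 map.
* `sigmoid`: σ(h) = 2/(1+e^{−ah}) − 1 (±1 map, implemented as
  tanh(ah/2)) or σ(h) = 1/(1+e^{−ah}) (0/1 map). The steepness a > 0
  controls how switch-like the response is; as a → ∞ both converge
  pointwise to the step function except at h = 0.

Zero net input (h_i = 0) has no canonical sign. The convention is
configurable and defaults to `minus` (gene goes to its off state);
alternatives are `plus`, `keep_previous`, and `quenched_random`, which
draws one tie-break sign per gene at matrix creation. A per-evaluation
random tie-break is deliberately not offered: it would make the update
stochastic and invalidate exact cycle detection. The conventions give
similar stability profiles, so the default is a reporting convention,
not a results driver. Note that with binary ±1 weights and odd K under
the ±1 map, net inputs are odd integers and the convention never fires.

## Attractor detection

Discrete case: every visited state is hashed with its time stamp; the
first revisit of a stored state at time t₀, seen again at time t, gives
transient t₀ and period t − t₀ exactly. Memory is O(t·N), and runs are
capped at t_max = min(2^N, max(10⁴, 100·N)) steps, with the additional
pigeonhole bound 2^N + 1 under which detection is guaranteed for small
N. Runs that exhaust t_max return `unresolved` — an outcome, not an
exception. A Brent (O(1)-memory) period finder is provided for very long
runs where the hash table would be costly; it does not report transients.

Continuous (sigmoid) case: a fixed point is declared when the max-norm
step change stays below eps = 10⁻⁶ for 10 consecutive steps; a cycle
when the state returns within eps of a checkpoint stored at power-of-two
times (so memory stays O(1)), with the checkpoint time as an upper bound
on the transient. The cycle check is suppressed while the trajectory is
quiet, otherwise a settled fixed point would match old checkpoints at
spurious periods > 1. The 2^N cap on t_max is not applied to continuous
runs (their state space is not finite); they use max(10⁴, 100·N).

Censoring accounting: unresolved runs count as non-fixed-point in S by
default — conservative for the claim that cycles dominate — and are
always reported separately; a strict mode (`censoring="drop"`) removes
them from Ω instead.

## Network ensembles

* `regular`: every gene has exactly K inputs, positions uniform without
  replacement (self-loops allowed by default; diagonal entries are
  self-regulation).
* `poisson`: in-degrees Poisson with mean K, truncated to [0, N] by
  rejection. Only the in-degree distribution is constrained — the
  in-degree is what enters the update — so out-degrees are emergent.
* `bio_exp_in_pow_out`: a parametric stand-in for transcriptional
  networks, with discretized-exponential in-degrees (mean K, truncated
  to [0, N]) and power-law out-degrees. The power-law exponent on
  {1..N} is solved by bisection in (1.5, 4) so the mean equals K; for
  degenerate tiny supports where no exponent in that bracket reaches
  the mean, the nearest bracket edge is used. Edges are placed by
  matching in-stubs to out-stubs: each row draws its K_i distinct
  sources with probability proportional to the drawn out-stub counts
  (duplicate pairings collapse and are re-drawn within the row), so
  in-degrees are exact and out-degrees heavy-tailed in expectation.

Weights are +1/−1 equiprobable (`binary_pm1`) or standard normal
(`real_gaussian`); a standard-normal draw is almost surely nonzero, so
density is controlled solely by topology. Initial states are uniform
over the 2^N discrete corners in both the ±1 and 0/1 conventions;
continuous runs also start from the corners.

## Exact enumeration

For small N the package enumerates the full binary regular matrix space
((C(N,K)·2^K)^N matrices) and the full state space (2^N states), giving
S exactly (se = 0) along with the complete per-matrix stability vector.
Enumerators are guarded by explicit size bounds and refuse with the
computed count. At N = 3, K = 3 (512 matrices × 8 states) the
per-matrix distribution is strongly bimodal: 300 matrices never reach a
fixed point and 88 always do, dominating every interior value.

## Attractor statistics

* Period distributions are tallied over resolved runs. Under the ±1 map,
  σ(W(−x)) = −σ(Wx) whenever no net input is zero, so the trajectory
  from −x₀ is the negation of the trajectory from x₀ and attractors pair
  up under negation; even-length cycles (which can be self-paired via a
  half-period shift) are overrepresented. Overrepresentation is
  operationalized as the frequency ratio f(L)/f(L+1) for even L,
  reported for L = 2, 4, 6.
* Decay fits: least squares of log-frequency against period
  (exponential) and against log-period (power law), with residual sums
  for comparison. Period 1 is excluded (these are cycle-length
  distributions), the even and odd branches are fitted separately for
  the ±1 map, and periods with fewer than 5 observations are dropped so
  tail noise does not dominate the unweighted log-space fit. A fit with
  fewer than 4 supported periods raises an error.
* Transient summaries average the transient over fixed-point runs only,
  per ensemble; cells with no observed fixed point are missing values,
  not failures. These curves are what motivate the t_max policy.
* Discovery curves sample pairs sequentially and record the sample index
  at which each new distinct fixed-point state (phenotype, pooled across
  matrices) appears, stopping at a target count or a sample cap;
  reaching the cap first is recorded as censoring.

## Seeding and reproducibility

Every sweep spawns one child of a master `numpy` SeedSequence per grid
point, so grid points are independently reproducible and there are no
seed collisions. Identical spec + seed gives bit-identical matrices,
trajectories and output tables.

## Problem sizes

Defaults are desk-scale: 10⁴ trials per sweep point (10⁵ for period
distributions), network sizes up to N = 20 for Monte Carlo and N = 3
for full enumeration. These sizes put binomial standard errors near
0.003–0.005 on S, small against every effect studied. All counts are
configurable through the recipe configs.

## What the generator does and does not emulate

The ensembles reproduce the degree structure, weight schemes and state
conventions studied in this model family. They are random ensembles:
real transcriptional networks are not random draws, and passing results
here say nothing about motif structure, correlated weights, or
empirically derived topologies (explicitly out of scope). Evolutionary
dynamics on populations of networks, asynchronous updates and
gene-specific thresholds are likewise out of scope.

## Known limitations

* Continuous-case periods and transients are tolerance-based and the
  reported transient is an upper bound (checkpoint time).
* The biological topology's out-degrees follow the power law in
  expectation, not exactly per draw (exact in-degrees were prioritized
  because the in-degree enters the dynamics).
* Monte Carlo S at very small values (large dense networks) needs large
  Ω for tight relative error; the sweep tables always carry Ω and se so
  under-resolved points are visible.
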