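"""Update rule, attractor detection, zero conventions, sigmoid limit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracle import census
from rtnstab import DynamicsSpec, RunLimits, iterate_to_attractor, netgen, step
from rtnstab.dynamics import brent_cycle_length, sigmoid_matches_sign, trajectory_states
from rtnstab.errors import ParameterError
from rtnstab.netgen import EnsembleSpec, WeightMatrix

ROTATION = np.array([[0.0, 1.0], [-1.0, 0.0]])


class TestStep:
    def test_identity_fixes_every_state(self, step_pm1):
        x = np.array([1.0, -1.0])
        assert (step(np.eye(2), x, step_pm1) == x).all()

    def test_negative_self_loop_flips(self, step_pm1):
        assert step(-np.eye(1), np.array([1.0]), step_pm1)[0] == -1.0

    def test_rotation_hand_evaluation(self, step_pm1):
        # h = (x2, -x1) so (+1,+1) -> (+1,-1)
        out = step(ROTATION, np.array([1.0, 1.0]), step_pm1)
        assert (out == [1.0, -1.0]).all()

    def test_dimension_mismatch(self, step_pm1):
        with pytest.raises(ParameterError):
            step(np.eye(3), np.array([1.0, 1.0]), step_pm1)

    @pytest.mark.parametrize("convention,expected", [
        ("minus", -1.0), ("plus", 1.0), ("keep_previous", 1.0)])
    def test_zero_input_conventions(self, convention, expected):
        spec = DynamicsSpec(map="pm1", zero_convention=convention)
        W = np.zeros((2, 2))   # every gene has zero net input
        out = step(W, np.array([1.0, 1.0]), spec)
        assert (out == expected).all()

    def test_quenched_ties_come_from_matrix(self, step_pm1):
        spec = DynamicsSpec(map="pm1", zero_convention="quenched_random")
        W = WeightMatrix(entries=np.zeros((3, 3)),
                         tie_signs=np.array([1, -1, 1]))
        out = step(W, np.array([-1.0, -1.0, -1.0]), spec)
        assert (out == [1.0, -1.0, 1.0]).all()

    def test_quenched_without_tie_signs_raises(self):
        spec = DynamicsSpec(map="pm1", zero_convention="quenched_random")
        with pytest.raises(ParameterError):
            step(np.zeros((2, 2)), np.array([1.0, 1.0]), spec)

    def test_zero_one_map_codomain(self, step_01):
        W = np.array([[1.0, -1.0], [-1.0, 1.0]])
        out = step(W, np.array([1.0, 0.0]), step_01)
        assert set(out) <= {0.0, 1.0}


class TestIterate:
    def test_identity_fixed_point(self, step_pm1, rng):
        for _ in range(5):
            x0 = netgen.random_initial_state(4, "pm1", rng)
            res = iterate_to_attractor(np.eye(4), x0, step_pm1)
            assert (res.outcome, res.period, res.transient) == ("fixed_point", 1, 0)

    def test_negation_two_cycle(self, step_pm1, rng):
        x0 = netgen.random_initial_state(3, "pm1", rng)
        res = iterate_to_attractor(-np.eye(3), x0, step_pm1)
        assert (res.outcome, res.period, res.transient) == ("cycle", 2, 0)

    def test_rotation_four_cycle(self, step_pm1):
        res = iterate_to_attractor(ROTATION, np.array([1.0, 1.0]), step_pm1)
        assert (res.outcome, res.period, res.transient) == ("cycle", 4, 0)

    def test_t_max_exhaustion_is_unresolved(self, rng):
        spec = DynamicsSpec(limits=RunLimits(t_max=2))
        W = netgen.generate_regular(EnsembleSpec(n_genes=8, k=8), rng)
        # rotation-rich dynamics rarely resolve in 2 steps; scan until censored
        for _ in range(50):
            x0 = netgen.random_initial_state(8, "pm1", rng)
            res = iterate_to_attractor(W, x0, spec)
            if res.outcome == "unresolved":
                assert res.period is None and res.steps_run == 2
                return
        pytest.fail("no censored run found")

    def test_default_t_max_policy(self):
        lim = RunLimits()
        assert lim.resolve_t_max(3, discrete=True) == 8
        assert lim.resolve_t_max(16, discrete=True) == 10_000
        assert lim.resolve_t_max(200, discrete=False) == 20_000

    @pytest.mark.parametrize("map", ["pm1", "zero_one"])
    def test_agrees_with_functional_graph_census(self, map, rng):
        """Exhaustive cross-check against an independent transition-graph
        analysis: outcome, period and transient for every state."""
        dyn = DynamicsSpec(map=map)
        for n in (2, 3, 4):
            for _ in range(25):
                k = int(rng.integers(1, n + 1))
                scheme = ["binary_pm1", "real_gaussian"][int(rng.integers(2))]
                W = netgen.generate_regular(
                    EnsembleSpec(n_genes=n, k=k, weight_scheme=scheme), rng)
                states, expected = census(W.entries, map=map)
                for x0, (outc, per, tr) in zip(states, expected):
                    res = iterate_to_attractor(W, x0, dyn)
                    assert (res.outcome, res.period, res.transient) == (outc, per, tr)

    def test_attractor_closure(self, step_pm1, rng):
        """One step applied to the last attractor state returns the first."""
        for _ in range(100):
            W = netgen.generate_regular(EnsembleSpec(n_genes=6, k=3), rng)
            x0 = netgen.random_initial_state(6, "pm1", rng)
            res = iterate_to_attractor(W, x0, step_pm1, keep_states=True)
            cyc = res.attractor_states
            assert len(cyc) == res.period
            for i in range(res.period):
                nxt = step(W, cyc[i], step_pm1)
                assert (nxt == cyc[(i + 1) % res.period]).all()
            assert res.transient + res.period <= res.steps_run + 1

    def test_fixed_point_iff_period_one(self, step_pm1, rng):
        for _ in range(200):
            W = netgen.generate_regular(
                EnsembleSpec(n_genes=5, k=5, weight_scheme="real_gaussian"), rng)
            x0 = netgen.random_initial_state(5, "pm1", rng)
            res = iterate_to_attractor(W, x0, step_pm1)
            fixed = (step(W, res.attractor_states[0], step_pm1)
                     == res.attractor_states[0]).all() if res.attractor_states else False
            assert (res.period == 1) == (res.outcome == "fixed_point")
            if res.outcome == "fixed_point":
                assert fixed

    def test_determinism(self, step_pm1):
        W = netgen.generate_regular(EnsembleSpec(n_genes=10, k=5),
                                    np.random.default_rng(3))
        x0 = netgen.random_initial_state(10, "pm1", np.random.default_rng(4))
        a = iterate_to_attractor(W, x0, step_pm1)
        b = iterate_to_attractor(W, x0, step_pm1)
        assert (a.outcome, a.period, a.transient) == (b.outcome, b.period, b.transient)

    def test_brent_agrees_on_period(self, step_pm1, rng):
        for _ in range(50):
            W = netgen.generate_regular(EnsembleSpec(n_genes=6, k=6), rng)
            x0 = netgen.random_initial_state(6, "pm1", rng)
            res = iterate_to_attractor(W, x0, step_pm1)
            assert brent_cycle_length(W, x0, step_pm1) == res.period


@st.composite
def gaussian_system(draw):
    n = draw(st.integers(min_value=2, max_value=6))
    seed = draw(st.integers(min_value=0, max_value=2 ** 31 - 1))
    r = np.random.default_rng(seed)
    W = r.standard_normal((n, n))
    x0 = r.integers(0, 2, n) * 2.0 - 1.0
    return W, x0


class TestAntisymmetry:
    """Under the +/-1 map with no zero net inputs, sigma(W(-x)) = -sigma(Wx)."""

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(gaussian_system())
    def test_trajectory_negation(self, sys):
        W, x0 = sys
        dyn = DynamicsSpec(map="pm1")
        a = trajectory_states(W, x0, dyn, 30)
        b = trajectory_states(W, -x0, dyn, 30)
        assert (b == -a).all()

    def test_equal_periods(self, step_pm1, rng):
        for _ in range(300):
            n = int(rng.integers(2, 8))
            W = rng.standard_normal((n, n))
            x0 = rng.integers(0, 2, n) * 2.0 - 1.0
            pa = iterate_to_attractor(W, x0, step_pm1).period
            pb = iterate_to_attractor(W, -x0, step_pm1).period
            assert pa == pb


class TestSigmoid:
    def test_codomain_and_step_limit(self):
        h = np.linspace(-3, 3, 101)
        for map, lo in (("pm1", -1.0), ("zero_one", 0.0)):
            spec = DynamicsSpec(map=map, norm="sigmoid", steepness=2.0)
            out = step(np.eye(101), h, spec)
            assert (out > lo).all() and (out < 1.0).all()
            assert (np.diff(out) > 0).all()    # nondecreasing in h
            steep = step(np.eye(101), h, spec.replace(steepness=500.0))
            on_off = DynamicsSpec(map=map, norm="step")
            hard = step(np.eye(101), h, on_off)
            mask = np.abs(h) > 0.05
            assert np.allclose(steep[mask], hard[mask], atol=1e-6)

    def test_continuous_fixed_point_detected(self):
        spec = DynamicsSpec(map="pm1", norm="sigmoid", steepness=100.0)
        res = iterate_to_attractor(np.eye(3), np.array([1.0, 1.0, -1.0]), spec)
        assert res.outcome == "fixed_point"
        assert np.allclose(np.abs(res.attractor_states[0]), 1.0, atol=1e-3)

    def test_continuous_cycle_detected(self):
        spec = DynamicsSpec(map="pm1", norm="sigmoid", steepness=100.0)
        res = iterate_to_attractor(ROTATION, np.array([1.0, 1.0]), spec)
        assert res.outcome == "cycle"
        assert res.period == 4

    def test_steep_sigmoid_shadows_sign(self, rng):
        for _ in range(20):
            W = netgen.generate_regular(EnsembleSpec(n_genes=7, k=3), rng)
            x0 = netgen.random_initial_state(7, "pm1", rng)
            assert sigmoid_matches_sign(W, x0, a=100.0, horizon=100)

    def test_identity_matches_for_any_steepness(self):
        x0 = np.ones(4)
        for a in (0.1, 1.0, 10.0):
            assert sigmoid_matches_sign(np.eye(4), x0, a=a, horizon=50)

    def test_even_k_rejected(self, rng):
        W = netgen.generate_regular(EnsembleSpec(n_genes=4, k=2), rng)
        with pytest.raises(ParameterError):
            sigmoid_matches_sign(W, np.ones(4), a=100.0, horizon=10)

    def test_shallow_sigmoid_contracts_to_interior(self):
        spec = DynamicsSpec(map="pm1", norm="sigmoid", steepness=0.01)
        traj = trajectory_states(-np.eye(1), np.array([1.0]), spec, 20)
        mags = np.abs(traj[:, 0])
        assert (np.diff(mags) < 0).all()
        assert mags[-1] < 1e-3
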