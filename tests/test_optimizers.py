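import numpy as np
import pytest
from scipy.stats import ks_2samp

import chaoelm as ce
from chaoelm.optimizers import (
    Candidate,
    ChaoticStream,
    OptimizerConfig,
    Population,
    cjaya_update,
    greedy_select,
    jaya_update,
    logistic_next,
    optimize,
    tlbo_learner_step,
    tlbo_teacher_step,
)


def sphere(z):
    return float(np.sum(np.square(z)))


class TestLogisticMap:
    @pytest.mark.parametrize("x,expected", [(0.5, 1.0), (0.75, 0.75), (0.2, 0.64)])
    def test_values(self, x, expected):
        assert logistic_next(x) == pytest.approx(expected, abs=1e-15)

    def test_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            logistic_next(1.5)
        with pytest.raises(ValueError):
            logistic_next(-0.1)


class TestChaoticStream:
    def test_range_preserved(self):
        stream = ChaoticStream(seed=0, dims=10)
        for _ in range(1000):
            x = stream.draw()
            assert np.all(x >= 0) and np.all(x <= 1)

    def test_determinism(self):
        a, b = ChaoticStream(seed=3, dims=4), ChaoticStream(seed=3, dims=4)
        for _ in range(50):
            np.testing.assert_array_equal(a.draw(), b.draw())

    def test_long_run_mean_near_half(self):
        # the invariant (arcsine) density of the logistic map at r=4 has mean 1/2
        stream = ChaoticStream(seed=1, dims=1)
        total = 0.0
        n = 100_000
        for _ in range(n):
            total += stream.draw()[0]
        assert abs(total / n - 0.5) < 0.01


class TestJayaUpdate:
    def test_zero_multipliers_identity(self):
        z = np.array([0.3, -0.4])
        out = jaya_update(z, np.ones(2), -np.ones(2), np.zeros(2), np.zeros(2))
        np.testing.assert_array_equal(out, z)

    def test_degenerate_population_fixed_point(self):
        z = np.array([0.2, 0.7])  # non-negative so |z| = z
        r = np.array([0.5, 0.9])
        np.testing.assert_allclose(jaya_update(z, z, z, r, r), z, atol=1e-15)

    def test_hand_case(self):
        out = jaya_update(
            np.array([0.5]), np.array([1.0]), np.array([-1.0]), np.array([1.0]), np.array([1.0])
        )
        assert out[0] == pytest.approx(2.5)

    def test_as_printed_flips_best_term(self):
        out = jaya_update(
            np.array([0.5]), np.array([1.0]), np.array([-1.0]),
            np.array([1.0]), np.array([1.0]), as_printed=True,
        )
        assert out[0] == pytest.approx(3.5)  # 0.5 + (1 + 0.5) - (-1 - 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaya_update(np.zeros(2), np.zeros(3), np.zeros(2), np.zeros(2), np.zeros(2))


class _StubStream:
    """Stream stand-in returning queued vectors (for forcing draws)."""

    def __init__(self, draws):
        self.draws = list(draws)

    def draw(self):
        return np.asarray(self.draws.pop(0), dtype=float)


class TestCJayaUpdate:
    def test_zero_draws_identity(self):
        z = np.array([0.1, -0.2])
        stream = _StubStream([np.zeros(2), np.zeros(2)])
        np.testing.assert_array_equal(cjaya_update(z, np.ones(2), -np.ones(2), stream), z)

    def test_equals_jaya_with_same_draws(self):
        z, zb, zw = np.array([0.2, -0.5]), np.array([0.9, 0.9]), np.array([-0.9, -0.9])
        s1 = ChaoticStream(seed=5, dims=2)
        s2 = ChaoticStream(seed=5, dims=2)
        r1, r2 = s2.draw(), s2.draw()
        np.testing.assert_array_equal(
            cjaya_update(z, zb, zw, s1), jaya_update(z, zb, zw, r1, r2)
        )

    def test_uniform_stub_reproduces_jaya_proposal_distribution(self):
        # with the chaotic stream stubbed by uniform draws, one-step CJaya
        # proposals are distributed exactly like Jaya proposals
        z, zb, zw = np.array([0.2]), np.array([0.8]), np.array([-0.7])
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(99)

        class UniformStream:
            def draw(self):
                return rng2.random(1)

        stream = UniformStream()
        n = 10_000
        jaya_props = np.array(
            [jaya_update(z, zb, zw, rng1.random(1), rng1.random(1))[0] for _ in range(n)]
        )
        cjaya_props = np.array([cjaya_update(z, zb, zw, stream)[0] for _ in range(n)])
        assert ks_2samp(jaya_props, cjaya_props).pvalue > 0.001


class _FakeRng:
    """Deterministic generator yielding preset integers/uniform vectors."""

    def __init__(self, integers=(), randoms=()):
        self._integers = list(integers)
        self._randoms = list(randoms)

    def integers(self, low, high, size=None):
        return self._integers.pop(0)

    def random(self, size=None):
        return np.asarray(self._randoms.pop(0), dtype=float)


class TestTlboSteps:
    def test_teacher_hand_case(self):
        # Z = {0, 1}, best = 1; Tf=1, mean=0.5, r=0.5 -> proposal for Z=0 is 0.25
        objective = lambda z: (1.0 - z[0]) ** 2
        pop = Population(
            z=np.array([[0.0], [1.0]]),
            objectives=np.array([1.0, 0.0]),
            lower=np.array([-2.0]),
            upper=np.array([2.0]),
        )
        rng = _FakeRng(integers=[1, 1], randoms=[[0.5], [0.0]])
        tlbo_teacher_step(pop, objective, rng)
        assert pop.z[0, 0] == pytest.approx(0.25)  # accepted: improves objective
        assert pop.z[1, 0] == pytest.approx(1.0)

    def test_teacher_degenerate_population_unchanged(self):
        objective = sphere
        pop = Population(
            z=np.full((3, 2), 0.4),
            objectives=np.full(3, sphere(np.full(2, 0.4))),
            lower=np.full(2, -1.0),
            upper=np.full(2, 1.0),
        )
        rng = _FakeRng(integers=[1, 1, 1], randoms=[[0.3, 0.3]] * 3)
        tlbo_teacher_step(pop, objective, rng)
        np.testing.assert_allclose(pop.z, 0.4)

    def test_learner_moves_toward_better_partner(self):
        objective = lambda z: (1.0 - z[0]) ** 2
        pop = Population(
            z=np.array([[0.0], [1.0]]),
            objectives=np.array([1.0, 0.0]),
            lower=np.array([-2.0]),
            upper=np.array([2.0]),
        )
        # candidate 0 partners with 1 (better): proposal 0 + 0.5*(1-0) = 0.5
        rng = _FakeRng(integers=[0, 0], randoms=[[0.5], [0.0]])
        tlbo_learner_step(pop, objective, rng)
        assert pop.z[0, 0] == pytest.approx(0.5)

    def test_zero_r_keeps_population(self):
        objective = sphere
        z0 = np.array([[0.3, -0.2], [0.6, 0.1]])
        pop = Population(
            z=z0.copy(),
            objectives=np.array([sphere(z0[0]), sphere(z0[1])]),
            lower=np.full(2, -1.0),
            upper=np.full(2, 1.0),
        )
        rng = _FakeRng(integers=[1, 2], randoms=[[0.0, 0.0]] * 2)
        tlbo_teacher_step(pop, objective, rng)
        np.testing.assert_array_equal(pop.z, z0)


class TestGreedySelect:
    def test_better_new_wins(self):
        old = Candidate(np.zeros(1), 1.0)
        new = Candidate(np.ones(1), 0.5)
        assert greedy_select(old, new) is new

    def test_tie_keeps_incumbent(self):
        old = Candidate(np.zeros(1), 1.0)
        new = Candidate(np.ones(1), 1.0)
        assert greedy_select(old, new) is old

    def test_unevaluated_rejected(self):
        with pytest.raises(ValueError):
            greedy_select(Candidate(np.zeros(1)), Candidate(np.ones(1), 0.0))


class TestOptimize:
    def test_constant_objective_flat_trace(self):
        cfg = OptimizerConfig(variant="jaya", dims=3, population=5, iterations=10, seed=0)
        best, trace = optimize(lambda z: 2.0, cfg)
        assert len(trace) == 11
        assert all(v == 2.0 for v in trace.best_objective)
        assert np.all(best.z >= -1) and np.all(best.z <= 1)

    @pytest.mark.parametrize("variant", ["jaya", "cjaya", "tlbo"])
    @pytest.mark.parametrize("seed", range(5))
    def test_elitism_and_bounds(self, variant, seed):
        seen = []

        def tracked(z):
            seen.append(z.copy())
            return sphere(z)

        cfg = OptimizerConfig(variant=variant, dims=4, population=10, iterations=15, seed=seed)
        best, trace = optimize(tracked, cfg)
        diffs = np.diff(trace.best_objective)
        assert np.all(diffs <= 1e-15)
        assert len(trace) == 16
        for z in seen:
            assert np.all(z >= -1 - 1e-12) and np.all(z <= 1 + 1e-12)
        assert best.objective == trace.best_objective[-1]

    def test_determinism(self):
        cfg = OptimizerConfig(variant="cjaya", dims=3, population=6, iterations=8, seed=12)
        b1, t1 = optimize(sphere, cfg)
        b2, t2 = optimize(sphere, cfg)
        np.testing.assert_array_equal(b1.z, b2.z)
        assert t1.best_objective == t2.best_objective

    def test_non_finite_objective_reported(self):
        cfg = OptimizerConfig(variant="jaya", dims=2, population=4, iterations=2, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda z: float("nan"), cfg)

    @pytest.mark.parametrize("variant", ["jaya", "cjaya", "tlbo"])
    def test_sphere_reduced(self, variant):
        cfg = OptimizerConfig(variant=variant, dims=5, population=30, iterations=60, seed=2)
        best, _ = optimize(sphere, cfg)
        assert best.objective < 0.05

    def test_trace_csv_export(self, tmp_path):
        cfg = OptimizerConfig(variant="jaya", dims=2, population=4, iterations=3, seed=0)
        _, trace = optimize(sphere, cfg)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns) == ["iteration", "best_objective"]
        assert len(frame) == 4
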