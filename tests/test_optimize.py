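"""εDE components and full optimizer runs."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from invqsar.optimize import (
    COProblem,
    DEParams,
    EpsilonDE,
    constraint_violation,
    epsilon_less,
    epsilon_schedule,
    evolve,
    exponential_crossover,
    mutate,
    reflect_to_bounds,
    round_discrete,
)


def make_problem(objective, bounds, ineqs=(), **kw) -> COProblem:
    return COProblem(objective=objective, bounds=np.asarray(bounds, float), inequalities=ineqs, **kw)


SPHERE = make_problem(lambda X: np.sum(X**2, axis=1), [(-5, 5)] * 3)


class TestConstraintViolation:
    def test_feasible_point_has_zero_violation(self):
        prob = make_problem(
            lambda X: X[:, 0],
            [(-1, 1)],
            ineqs=[lambda X: X[:, 0] - 1, lambda X: -X[:, 0] - 1],
        )
        assert constraint_violation(np.array([0.0]), prob) == 0.0

    @pytest.mark.parametrize("p, expected", [(1.0, 0.75), (2.0, 0.3125)])
    def test_printed_arithmetic_cases(self, p, expected):
        # g = (0.5, -1), h = (-0.25)
        prob = COProblem(
            objective=lambda X: np.zeros(len(X)),
            bounds=np.array([[-10.0, 10.0]]),
            inequalities=[
                lambda X: np.full(len(X), 0.5),
                lambda X: np.full(len(X), -1.0),
            ],
            equalities=[lambda X: np.full(len(X), -0.25)],
        )
        assert constraint_violation(np.array([0.0]), prob, p=p) == pytest.approx(
            expected, abs=0
        )

    def test_nonfinite_constraint_names_index(self):
        prob = COProblem(
            objective=lambda X: np.zeros(len(X)),
            bounds=np.array([[-1.0, 1.0]]),
            inequalities=[
                lambda X: np.zeros(len(X)),
                lambda X: np.full(len(X), np.nan),
            ],
        )
        with pytest.raises(ValueError, match="constraint 1"):
            constraint_violation(np.array([0.0]), prob)


class TestEpsilonSchedule:
    def test_tc_one_vanishes_from_first_generation(self):
        for t in (1, 2, 10, 10_000):
            assert epsilon_schedule(t, epsilon0=3.7, Tc=1, cp=5) == 0.0

    def test_initial_level_is_epsilon0(self):
        assert epsilon_schedule(0, epsilon0=3.7, Tc=100, cp=5) == 3.7

    def test_linear_decay_midpoint(self):
        assert epsilon_schedule(50, epsilon0=2.0, Tc=100, cp=1) == pytest.approx(1.0)


class TestEpsilonLess:
    @pytest.mark.parametrize(
        "a, b, eps, expected",
        [
            ((1, 0), (2, 0), 0.0, True),  # both feasible: compare f
            ((1, 0.3), (5, 0.3), 0.0, True),  # equal violation: compare f
            ((0, 0.4), (100, 0.1), 0.0, False),  # otherwise: compare violation
            ((5, 0.05), (1, 0.08), 0.1, False),  # both within eps: compare f
        ],
    )
    def test_truth_table(self, a, b, eps, expected):
        assert epsilon_less(a, b, eps) is expected

    @given(
        f1=st.floats(-10, 10),
        f2=st.floats(-10, 10),
        phi1=st.floats(0, 5),
        phi2=st.floats(0, 5),
        eps=st.floats(0, 5),
    )
    def test_asymmetry(self, f1, f2, phi1, phi2, eps):
        """a < b and b < a can never hold simultaneously."""
        assert not (
            epsilon_less((f1, phi1), (f2, phi2), eps)
            and epsilon_less((f2, phi2), (f1, phi1), eps)
        )


class TestMutation:
    def test_zero_difference_returns_base_vector(self):
        # rows 1..3 identical, so x_r2 - x_r3 = 0 and v = x_r1 always
        pop = np.array([[5.0, 5.0], [2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        rng = np.random.default_rng(0)
        for _ in range(10):
            np.testing.assert_array_equal(mutate(pop, 0, F=0.7, rng=rng), [2.0, 2.0])

    def test_hand_case(self):
        pop = np.array([[9.0, 9.0], [0.0, 0.0], [2.0, 2.0], [0.0, 0.0]])

        class FixedRng:
            def choice(self, pool, size, replace):
                return np.array([1, 2, 3])

        v = mutate(pop, 0, F=0.5, rng=FixedRng())
        np.testing.assert_allclose(v, [1.0, 1.0])

    def test_indices_exclude_target_and_are_distinct(self):
        pop = np.random.default_rng(0).normal(size=(6, 1))
        rng = np.random.default_rng(1)
        # brute-force check via many draws on a population of distinct scalars
        for _ in range(200):
            v = mutate(pop, 2, F=0.0, rng=rng)  # F=0 -> v == x_r1
            assert not np.allclose(v, pop[2])

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            mutate(np.zeros((3, 2)), 0, 0.5, np.random.default_rng(0))


class TestReflection:
    @pytest.mark.parametrize(
        "v, lo, hi, expected",
        [
            (-2.0, 0.0, 10.0, 2.0),  # reflection about the lower bound
            (-5.0, 0.0, 1.0, 1.0),  # reflected past the upper bound: capped
            (0.5, 0.0, 1.0, 0.5),  # in-bounds untouched
            (12.0, 0.0, 10.0, 8.0),  # reflection about the upper bound
        ],
    )
    def test_hand_cases(self, v, lo, hi, expected):
        out = reflect_to_bounds(np.array([v]), np.array([[lo, hi]]))
        assert out[0] == pytest.approx(expected)

    @given(
        v=st.floats(-100, 100),
        lo=st.floats(-10, 0),
        width=st.floats(0.1, 10),
    )
    def test_output_always_within_bounds(self, v, lo, width):
        out = reflect_to_bounds(np.array([v]), np.array([[lo, lo + width]]))
        assert lo - 1e-12 <= out[0] <= lo + width + 1e-12


class TestCrossover:
    def test_cr_zero_copies_exactly_one_component(self):
        rng = np.random.default_rng(0)
        target = np.zeros(6)
        donor = np.ones(6)
        for _ in range(10):
            trial = exponential_crossover(target, donor, CR=0.0, rng=rng)
            assert trial.sum() == 1.0

    def test_cr_one_copies_everything(self):
        rng = np.random.default_rng(0)
        trial = exponential_crossover(np.zeros(6), np.ones(6), CR=1.0, rng=rng)
        np.testing.assert_array_equal(trial, np.ones(6))

    def test_identical_vectors_unchanged(self):
        x = np.arange(4.0)
        trial = exponential_crossover(x, x.copy(), CR=0.5, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(trial, x)

    def test_copied_block_is_circularly_contiguous(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            trial = exponential_crossover(np.zeros(8), np.ones(8), CR=0.7, rng=rng)
            ones = set(np.flatnonzero(trial == 1.0))
            if len(ones) == 8:
                continue
            # a single circular block has exactly one member whose
            # predecessor (mod d) is not in the block
            starts = sum(1 for p in ones if (p - 1) % 8 not in ones)
            assert starts == 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            exponential_crossover(np.zeros(2), np.zeros(3), 0.5, np.random.default_rng(0))


def test_round_discrete_half_away_from_zero():
    v = np.array([1.5, -1.5, 1.5, 0.49])
    mask = np.array([True, True, False, True])
    np.testing.assert_array_equal(round_discrete(v, mask), [2.0, -2.0, 1.5, 0.0])


class TestEvolve:
    def test_sphere_reaches_near_zero(self):
        rng = np.random.default_rng(0)
        X0 = rng.uniform(-5, 5, size=(50, 3))
        result = evolve(SPHERE, DEParams(n_generations=200, seed=0), X0)
        assert result.best.f_value < 1e-3
        assert result.feasible

    def test_linear_program_finds_constraint_boundary(self):
        prob = make_problem(
            lambda X: -(X[:, 0] + X[:, 1]),
            [(0, 1), (0, 1)],
            ineqs=[lambda X: X[:, 0] + X[:, 1] - 1.0],
        )
        X0 = np.random.default_rng(1).uniform(0, 1, size=(40, 2))
        result = evolve(prob, DEParams(n_generations=300, seed=1), X0)
        assert result.best.phi == 0.0
        assert result.best.f_value == pytest.approx(-1.0, abs=1e-6)

    def test_history_monotone_once_feasible(self):
        X0 = np.random.default_rng(2).uniform(-5, 5, size=(30, 3))
        result = evolve(SPHERE, DEParams(n_generations=100, seed=2), X0)
        f = result.history[:, 0]
        assert np.all(np.diff(f) <= 1e-12)

    def test_best_always_within_bounds(self):
        X0 = np.random.default_rng(3).uniform(-5, 5, size=(20, 3))
        result = evolve(SPHERE, DEParams(n_generations=50, seed=3), X0)
        assert np.all(result.best.x >= -5) and np.all(result.best.x <= 5)

    def test_discrete_mask_yields_integral_solution(self):
        prob = make_problem(
            lambda X: np.sum((X - 0.2) ** 2, axis=1),
            [(-5, 5)] * 2,
            discrete_mask=np.array([True, False]),
        )
        X0 = np.random.default_rng(4).uniform(-5, 5, size=(20, 2))
        result = evolve(prob, DEParams(n_generations=100, seed=4), X0)
        assert result.best.x[0] == np.round(result.best.x[0])
        assert result.best.f_value == pytest.approx(0.04, abs=1e-4)

    def test_infeasible_problem_flagged_not_raised(self):
        prob = make_problem(
            lambda X: np.sum(X**2, axis=1),
            [(-1, 1)] * 2,
            ineqs=[lambda X: np.full(len(X), 1.0)],  # never satisfiable
        )
        X0 = np.random.default_rng(5).uniform(-1, 1, size=(10, 2))
        result = evolve(prob, DEParams(n_generations=20, seed=5), X0)
        assert not result.feasible

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            evolve(SPHERE, DEParams(n_generations=1), np.zeros((3, 3)))

    def test_wrapper_class_equivalent(self):
        X0 = np.random.default_rng(6).uniform(-5, 5, size=(20, 3))
        a = evolve(SPHERE, DEParams(n_generations=30, seed=6), X0)
        b = EpsilonDE(DEParams(n_generations=30, seed=6)).solve(SPHERE, X0)
        np.testing.assert_array_equal(a.best.x, b.best.x)

    def test_simulation_pipeline_exceeds_training_predictions(self, sim_trials):
        """Optimized coordinates beat every training-point prediction and
        stay inside the applicability domain."""
        for trial in sim_trials:
            opt = trial["opt"]
            assert opt.predicted_activity >= trial["train_pred_max"] - 1e-9
            assert opt.ad_score >= 0.0


def _plain_de_reference(objective, bounds, X0, F, CR, n_gen, seed):
    """Independent canonical DE/rand/1/exp (greedy selection, no
    constraints), consuming random draws in the documented order."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    X = X0.copy()
    n, d = X.shape
    fx = np.array([objective(x[None, :])[0] for x in X])
    for _ in range(n_gen):
        idx = rng.integers(0, n, size=(n, 3))
        rows = np.arange(n)
        while True:
            bad = (
                (idx[:, 0] == idx[:, 1])
                | (idx[:, 0] == idx[:, 2])
                | (idx[:, 1] == idx[:, 2])
                | (idx == rows[:, None]).any(axis=1)
            )
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), 3))
        starts = rng.integers(0, d, size=n)
        u = rng.random((n, d - 1))
        Xs = X.copy()  # donors come from the generation-start population
        for i in range(n):
            v = Xs[idx[i, 0]] + F * (Xs[idx[i, 1]] - Xs[idx[i, 2]])
            below, above = v < lo, v > hi
            v[below] = np.minimum(hi[below], 2 * lo[below] - v[below])
            v[above] = np.maximum(lo[above], 2 * hi[above] - v[above])
            trial = Xs[i].copy()
            pos, copied = int(starts[i]), 0
            while True:
                trial[pos] = v[pos]
                copied += 1
                if copied >= d or u[i, copied - 1] >= CR:
                    break
                pos = (pos + 1) % d
            ft = objective(trial[None, :])[0]
            if ft < fx[i]:
                X[i] = trial
                fx[i] = ft
    return X, fx


def test_reduces_to_canonical_de_without_constraints():
    """With no constraints εDE is canonical DE/rand/1/exp: a seed-matched
    independent implementation produces a bitwise-identical population."""
    rng = np.random.default_rng(7)
    X0 = rng.uniform(-5, 5, size=(20, 3))
    objective = lambda X: np.sum(np.atleast_2d(X) ** 2, axis=1)
    prob = make_problem(objective, [(-5, 5)] * 3)
    result = evolve(prob, DEParams(F=0.5, CR=0.9, n_generations=40, seed=42), X0)
    X_ref, f_ref = _plain_de_reference(
        objective, prob.bounds, X0, F=0.5, CR=0.9, n_gen=40, seed=42
    )
    assert result.best.f_value == pytest.approx(f_ref.min(), abs=0)
    best_ref = X_ref[np.argmin(f_ref)]
    np.testing.assert_array_equal(result.best.x, best_ref)
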