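"""ε-constrained differential evolution (εDE) for constrained optimization.

The optimizer solves

    minimize f(x)
    s.t.     g_j(x) <= 0   (j = 1..q)
             h_j(x) = 0    (j = q+1..m)
             l_i <= x_i <= u_i

by DE/rand/1 mutation with exponential crossover and one-to-one ε-level
selection.  The aggregate constraint violation is

    Φ(x) = Σ_j max(0, g_j(x))^p + Σ_j |h_j(x)|^p

and two (f, Φ) pairs are ordered by f when both violations are within the
current tolerance ε(t) (or exactly equal), and by Φ otherwise.  The
tolerance starts at the violation of the top-θ individual of the initial
population and decays to zero at generation Tc; with the default Tc = 1 the
tolerance applies only to the first offspring round.

Objective and constraint callables are evaluated batchwise: they receive an
(n, d) array and must return a length-n array.  Use
:meth:`COProblem.from_scalar` to wrap plain scalar functions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np


@dataclasses.dataclass
class COProblem:
    """A constrained optimization problem over a box.

    ``objective``, ``inequalities`` and ``equalities`` take an (n, d) array
    and return a length-n array.  Feasibility means every inequality is
    <= 0 and every equality is 0.  ``discrete_mask`` marks dimensions that
    are rounded to integers after mutation; ``quantize``, when given,
    replaces that default rounding (used when discreteness lives in another
    coordinate system, e.g. unscaled descriptor units).
    """

    objective: Callable[[np.ndarray], np.ndarray]
    bounds: np.ndarray
    inequalities: Sequence[Callable[[np.ndarray], np.ndarray]] = ()
    equalities: Sequence[Callable[[np.ndarray], np.ndarray]] = ()
    discrete_mask: Optional[np.ndarray] = None
    quantize: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2 or self.bounds.shape[0] < 1:
            raise ValueError("bounds must be a (d, 2) array")
        if np.any(self.bounds[:, 0] > self.bounds[:, 1]):
            raise ValueError("each lower bound must be <= its upper bound")
        if self.discrete_mask is not None:
            self.discrete_mask = np.asarray(self.discrete_mask, dtype=bool)
            if self.discrete_mask.shape != (self.dim,):
                raise ValueError("discrete_mask must have length d")

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    @classmethod
    def from_scalar(
        cls,
        objective: Callable[[np.ndarray], float],
        bounds,
        inequalities: Sequence[Callable[[np.ndarray], float]] = (),
        equalities: Sequence[Callable[[np.ndarray], float]] = (),
        **kwargs,
    ) -> "COProblem":
        """Build a problem from scalar callables of a single d-vector."""

        def batch(fn):
            return lambda X: np.array([float(fn(row)) for row in np.atleast_2d(X)])

        return cls(
            objective=batch(objective),
            bounds=bounds,
            inequalities=[batch(g) for g in inequalities],
            equalities=[batch(h) for h in equalities],
            **kwargs,
        )


@dataclasses.dataclass(frozen=True)
class DEParams:
    """εDE control parameters.

    Defaults follow the standard inverse-QSAR settings: F = 0.5, CR = 0.9,
    p = 1, Tc = 1.  ``theta`` fixes ε(0) as the violation of the individual
    at ascending-Φ rank ⌈θN⌉; ``cp`` shapes the ε decay and is irrelevant
    when Tc = 1.
    """

    F: float = 0.5
    CR: float = 0.9
    p: float = 1.0
    Tc: int = 1
    cp: float = 5.0
    theta: float = 0.2
    n_generations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be positive")
        if not 0 <= self.CR <= 1:
            raise ValueError("CR must lie in [0, 1]")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.Tc < 1:
            raise ValueError("Tc must be >= 1")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must lie in (0, 1]")
        if self.n_generations < 0:
            raise ValueError("n_generations must be non-negative")


@dataclasses.dataclass
class Individual:
    """A candidate vector with cached objective value and violation."""

    x: np.ndarray
    f_value: float
    phi: float


@dataclasses.dataclass
class OptimizationResult:
    """Outcome of an εDE run.

    ``best`` is the best individual over every vector ever evaluated, under
    the ε = 0 comparison (feasible points always beat infeasible ones).
    ``history`` holds the per-generation population best as (f, Φ) rows.
    """

    best: Individual
    history: np.ndarray
    generations_run: int
    converged: bool

    @property
    def feasible(self) -> bool:
        return self.best.phi == 0.0


def constraint_violation(x, problem: COProblem, p: float = 1.0) -> np.ndarray | float:
    """Aggregate violation Φ(x) = Σ max(0, g_j)^p + Σ |h_j|^p.

    Accepts a single d-vector or an (n, d) batch.  Φ = 0 iff x is feasible.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    phi = np.zeros(X.shape[0])
    for j, g in enumerate(problem.inequalities):
        vals = np.asarray(g(X), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"inequality constraint {j} returned a non-finite value")
        phi += np.maximum(0.0, vals) ** p
    for j, h in enumerate(problem.equalities):
        vals = np.asarray(h(X), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"equality constraint {j} returned a non-finite value")
        phi += np.abs(vals) ** p
    if np.asarray(x).ndim == 1:
        return float(phi[0])
    return phi


def epsilon_schedule(t: int, epsilon0: float, Tc: int, cp: float) -> float:
    """Violation tolerance ε(t): ε0 at t=0, decaying to 0 at generation Tc."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return float(epsilon0)
    if t < Tc:
        return float(epsilon0) * (1.0 - t / Tc) ** cp
    return 0.0


def epsilon_less(a: tuple[float, float], b: tuple[float, float], eps: float) -> bool:
    """ε-level order on (f, Φ) pairs: objective first while both violations
    are within ε (or exactly tied), violation otherwise."""
    f1, phi1 = a
    f2, phi2 = b
    if (phi1 <= eps and phi2 <= eps) or phi1 == phi2:
        return f1 < f2
    return phi1 < phi2


def mutate(population, i: int, F: float, rng: np.random.Generator) -> np.ndarray:
    """DE/rand/1 donor: x_r1 + F (x_r2 - x_r3), r1 != r2 != r3 != i."""
    X = np.asarray(
        [ind.x if isinstance(ind, Individual) else ind for ind in population],
        dtype=float,
    )
    n = X.shape[0]
    if n < 4:
        raise ValueError("population must contain at least 4 individuals")
    pool = np.delete(np.arange(n), i)
    r1, r2, r3 = rng.choice(pool, size=3, replace=False)
    return X[r1] + F * (X[r2] - X[r3])


def reflect_to_bounds(v, bounds) -> np.ndarray:
    """Reflect out-of-bounds components about the violated bound.

    v_i < l_i -> min(u_i, 2 l_i - v_i); v_i > u_i -> max(l_i, 2 u_i - v_i).
    The output always lies within the box.
    """
    v = np.asarray(v, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[..., 0], bounds[..., 1]
    out = v.copy()
    low = out < lo
    out = np.where(low, np.minimum(hi, 2 * lo - out), out)
    high = out > hi
    out = np.where(high, np.maximum(lo, 2 * hi - out), out)
    return out


def exponential_crossover(
    target, donor, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Classic DE exponential crossover.

    A start position is drawn uniformly; donor components are copied
    circularly from there while successive uniform draws stay below CR, at
    least one component always coming from the donor.
    """
    target = np.asarray(target, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if target.shape != donor.shape:
        raise ValueError("target and donor dimensions differ")
    d = target.shape[0]
    trial = target.copy()
    pos = int(rng.integers(0, d))
    copied = 0
    while True:
        trial[pos] = donor[pos]
        copied += 1
        if copied >= d or rng.random() >= CR:
            break
        pos = (pos + 1) % d
    return trial


def round_discrete(v, mask) -> np.ndarray:
    """Round masked components half-away-from-zero; leave others untouched."""
    v = np.asarray(v, dtype=float)
    if mask is None:
        return v.copy()
    mask = np.asarray(mask, dtype=bool)
    rounded = np.copysign(np.floor(np.abs(v) + 0.5), v)
    return np.where(mask, rounded, v)


def _crossover_masks(
    n: int, d: int, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n, d) donor masks matching exponential crossover.

    Draw protocol per generation: start positions ``rng.integers(0, d, n)``,
    then a uniform block ``rng.random((n, d - 1))``; the run length is one
    plus the count of leading draws below CR.
    """
    starts = rng.integers(0, d, size=n)
    if d == 1:
        return np.ones((n, 1), dtype=bool)
    u = rng.random((n, d - 1))
    stop = u >= CR
    # length = 1 + index of first stop (d-1+1 = d if no stop)
    first_stop = np.where(stop.any(axis=1), stop.argmax(axis=1), d - 1)
    lengths = first_stop + 1
    offsets = np.arange(d)
    pos = (starts[:, None] + offsets[None, :]) % d
    mask = np.zeros((n, d), dtype=bool)
    take = offsets[None, :] < lengths[:, None]
    mask[np.repeat(np.arange(n), d)[take.ravel()], pos[take]] = True
    return mask


def _mutation_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) donor indices, rows distinct and different from the row number.

    Vectorized rejection sampling: invalid rows are redrawn until clean;
    deterministic given the generator state.
    """
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
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), 3))


def _quantize_batch(problem: COProblem, V: np.ndarray) -> np.ndarray:
    if problem.quantize is not None:
        return np.asarray(problem.quantize(V), dtype=float)
    if problem.discrete_mask is not None and problem.discrete_mask.any():
        return round_discrete(V, problem.discrete_mask)
    return V


def _evaluate(problem: COProblem, X: np.ndarray, p: float) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(problem.objective(X), dtype=float)
    if f.shape != (X.shape[0],):
        raise ValueError("objective must return one value per row")
    phi = np.asarray(constraint_violation(X, problem, p), dtype=float)
    return f, phi


def _better0(f1: float, phi1: float, f2: float, phi2: float) -> bool:
    return epsilon_less((f1, phi1), (f2, phi2), 0.0)


def evolve(
    problem: COProblem,
    params: DEParams,
    initial_population,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Run εDE from an explicit initial population.

    Per generation: DE/rand/1 mutation, reflection into bounds, discrete
    rounding, exponential crossover, then one-to-one replacement under the
    ε(t) comparison (ties retain the parent).  Draws per generation, in
    order: mutation index block, crossover start positions, crossover
    uniforms (see :func:`_mutation_indices` and :func:`_crossover_masks`).

    The returned best is tracked over every evaluated vector under the
    ε = 0 comparison; if no feasible point was ever seen the result is
    flagged infeasible (``result.feasible`` is False), not an error.
    Convergence reports whether the final population has collapsed to a
    single point (max pairwise ∞-norm spread < 1e-6); the full generation
    budget is always executed.
    """
    X = np.atleast_2d(np.asarray(initial_population, dtype=float)).copy()
    n, d = X.shape
    if d != problem.dim:
        raise ValueError("initial population dimensionality mismatch")
    if n < 4:
        raise ValueError("population must contain at least 4 individuals")
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    for i in range(n):
        X[i] = reflect_to_bounds(X[i], problem.bounds)
    X = np.clip(_quantize_batch(problem, X), problem.bounds[:, 0], problem.bounds[:, 1])

    f, phi = _evaluate(problem, X, params.p)

    # ε(0) = Φ of the individual at ascending-violation rank ⌈θN⌉
    rank = min(n, max(1, math.ceil(params.theta * n))) - 1
    epsilon0 = float(np.sort(phi)[rank])

    # With Φ >= 0 the ε = 0 order coincides with lexicographic (Φ, f);
    # np.lexsort is stable, so ties keep the earliest individual.
    best_i = int(np.lexsort((f, phi))[0])
    best = Individual(x=X[best_i].copy(), f_value=float(f[best_i]), phi=float(phi[best_i]))

    history = np.empty((params.n_generations, 2))
    for t in range(params.n_generations):
        eps = epsilon_schedule(t, epsilon0, params.Tc, params.cp)
        idx = _mutation_indices(n, rng)
        V = X[idx[:, 0]] + params.F * (X[idx[:, 1]] - X[idx[:, 2]])
        V = reflect_to_bounds(V, problem.bounds)
        V = np.clip(
            _quantize_batch(problem, V), problem.bounds[:, 0], problem.bounds[:, 1]
        )
        masks = _crossover_masks(n, d, params.CR, rng)
        trials = np.where(masks, V, X)
        f_t, phi_t = _evaluate(problem, trials, params.p)

        both_ok = (phi_t <= eps) & (phi <= eps)
        replace = np.where(
            both_ok | (phi_t == phi), f_t < f, phi_t < phi
        )
        X[replace] = trials[replace]
        f[replace] = f_t[replace]
        phi[replace] = phi_t[replace]

        cand = int(np.lexsort((f_t, phi_t))[0])
        if _better0(f_t[cand], phi_t[cand], best.f_value, best.phi):
            best = Individual(
                x=trials[cand].copy(), f_value=float(f_t[cand]), phi=float(phi_t[cand])
            )

        gen_best = int(np.lexsort((f, phi))[0])
        history[t] = (f[gen_best], phi[gen_best])

    spread = float(np.max(X.max(axis=0) - X.min(axis=0))) if n > 1 else 0.0
    return OptimizationResult(
        best=best,
        history=history,
        generations_run=params.n_generations,
        converged=spread < 1e-6,
    )


class EpsilonDE:
    """Thin object wrapper over :func:`evolve` holding a parameter set."""

    def __init__(self, params: Optional[DEParams] = None, **overrides):
        base = params if params is not None else DEParams()
        self.params = dataclasses.replace(base, **overrides) if overrides else base

    def solve(
        self,
        problem: COProblem,
        initial_population,
        rng: Optional[np.random.Generator] = None,
    ) -> OptimizationResult:
        return evolve(problem, self.params, initial_population, rng=rng)
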