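"""Continuous Chaos Game Optimization (CGO).

CGO is a population metaheuristic inspired by the chaos game used to draw
fractals such as the Sierpinski triangle.  Each solution candidate (a
"seed" ``S_k`` in the box ``[L, U]^dim``) forms a temporary triangle with
the global best ``G`` and the mean ``M_k`` of a randomly chosen subgroup
of the population.  Four candidate points are generated from each
triangle:

    P1 = S_k + alpha * (beta * G   - gamma * M_k)
    P2 = G   + alpha * (beta * S_k - gamma * M_k)
    P3 = M_k + alpha * (beta * S_k - gamma * G)
    P4 = S_k with a uniform(0, 1) perturbation on a random subset of
         dimensions

with ``alpha`` drawn from one of four randomly chosen formulas
(``R``, ``2R``, ``eps*R + 1``, ``eps*R + eps``; ``R``, ``eps`` uniform on
(0, 1)) and ``beta``, ``gamma`` random integers from a two-element domain.
Candidates are clipped to the box, evaluated, and pooled with the
incumbents; the best ``D`` survive (minimization convention throughout).

The module also ships the classic chaos-game construction of the
Sierpinski triangle, which serves as a geometric validation of the
random-midpoint machinery the optimizer is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Objective = Callable[[np.ndarray], float]

_ADMISSIBLE_BETA_GAMMA = ((0, 1), (1, 2))


@dataclass(frozen=True)
class CGOParams:
    """Configuration of one CGO run.

    Parameters
    ----------
    dim : int
        Dimensionality of the search box.
    population_size : int, default 50
        Number of solution candidates ``D`` kept at all times.
    max_iterations : int, default 100
        Fixed iteration budget; the only termination rule.
    lower_bound, upper_bound : float or array of shape (dim,)
        Box constraints ``L <= x <= U`` (elementwise).
    beta_gamma_domain : tuple, default (1, 2)
        Two-element integer domain the die factors ``beta``/``gamma`` are
        drawn from; ``(0, 1)`` is the admissible alternative.
    mean_group_size : int or None
        Fixed subgroup size for ``M_k``; ``None`` draws the size uniformly
        from ``{1, ..., D}`` for every seed.
    alpha_per_dimension : bool, default False
        Draw ``alpha`` once per candidate point (scalar, default) or
        independently per coordinate.
    rng_seed : int, default 0
        Seed of the single generator driving the whole run.
    """

    dim: int
    population_size: int = 50
    max_iterations: int = 100
    lower_bound: float | np.ndarray = 0.0
    upper_bound: float | np.ndarray = 1.0
    beta_gamma_domain: tuple[int, int] = (1, 2)
    mean_group_size: int | None = None
    alpha_per_dimension: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.population_size < 2:
            raise ValueError(
                f"population_size must be >= 2, got {self.population_size}"
            )
        if self.max_iterations < 1:
            raise ValueError(
                f"max_iterations must be >= 1, got {self.max_iterations}"
            )
        lo, hi = self.bounds()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo > hi):
            raise ValueError("lower_bound must be <= upper_bound elementwise")
        if tuple(self.beta_gamma_domain) not in _ADMISSIBLE_BETA_GAMMA:
            raise ValueError(
                "beta_gamma_domain must be (0, 1) or (1, 2), "
                f"got {self.beta_gamma_domain}"
            )
        if self.mean_group_size is not None and not (
            1 <= self.mean_group_size <= self.population_size
        ):
            raise ValueError("mean_group_size must be in {1, ..., D}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper bounds broadcast to shape ``(dim,)``."""
        lo = np.broadcast_to(np.asarray(self.lower_bound, float), (self.dim,))
        hi = np.broadcast_to(np.asarray(self.upper_bound, float), (self.dim,))
        return lo.copy(), hi.copy()


@dataclass
class SeedPopulation:
    """The ``D`` candidate solutions with their fitness and the global best."""

    positions: np.ndarray  # (D, dim)
    fitness: np.ndarray  # (D,)
    global_best: np.ndarray  # (dim,)
    global_best_fitness: float

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.fitness = np.asarray(self.fitness, float)
        if self.positions.shape[0] != self.fitness.shape[0]:
            raise ValueError("positions and fitness lengths differ")

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class TriangleSeeds:
    """The four candidate points generated from one temporary triangle."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.p1, self.p2, self.p3, self.p4])


@dataclass
class OptimizerTrace:
    """Best-so-far fitness per iteration plus evaluation accounting."""

    best_fitness_per_iteration: np.ndarray
    evaluations_used: int
    final_best_position: np.ndarray
    initial_evaluations: int = 0

    def cumulative_evaluations(self) -> np.ndarray:
        """Objective calls spent up to and including each iteration."""
        d = len(self.best_fitness_per_iteration)
        per_iter = (self.evaluations_used - self.initial_evaluations) // max(d, 1)
        return self.initial_evaluations + per_iter * np.arange(1, d + 1)


def alpha_formulas(r: float, eps: float) -> tuple[float, float, float, float]:
    """The four candidate values of the mobility factor for given draws."""
    return (r, 2.0 * r, eps * r + 1.0, eps * r + eps)


def sample_alpha(rng: np.random.Generator, size: int | None = None):
    """Draw the mobility limitation factor ``alpha``.

    One of the four formulas ``{R, 2R, eps*R + 1, eps*R + eps}`` is picked
    uniformly, with ``R`` and ``eps`` fresh uniform draws on (0, 1).  With
    ``size`` given, every coordinate gets an independent draw.

    Draw order per scalar value: formula index, then R, then eps.
    """
    if size is None:
        idx = int(rng.integers(4))
        r = float(rng.random())
        eps = float(rng.random())
        return alpha_formulas(r, eps)[idx]
    return np.array([sample_alpha(rng) for _ in range(size)])


def initialize_population(
    params: CGOParams,
    objective: Objective,
    rng: np.random.Generator | None = None,
) -> SeedPopulation:
    """Uniform initialization ``X = rand * (U - L) + L`` plus evaluation."""
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    lo, hi = params.bounds()
    positions = rng.random((params.population_size, params.dim)) * (hi - lo) + lo
    fitness = _evaluate_all(objective, positions)
    best = int(np.argmin(fitness))
    return SeedPopulation(
        positions=positions,
        fitness=fitness,
        global_best=positions[best].copy(),
        global_best_fitness=float(fitness[best]),
    )


def _evaluate_all(objective: Objective, positions: np.ndarray) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        v = float(objective(x))
        if not np.isfinite(v):
            raise ValueError(
                f"objective returned non-finite value {v!r} at position {x.tolist()}"
            )
        out[i] = v
    return out


def mean_group(
    population: SeedPopulation,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Centroid ``M_k`` of a randomly chosen subgroup of the population.

    The subgroup size defaults to a uniform draw from ``{1, ..., D}``;
    members are sampled without replacement.
    """
    d = population.size
    if d == 0:
        raise ValueError("population is empty")
    if size is None:
        size = int(rng.integers(1, d + 1))
    if not 1 <= size <= d:
        raise ValueError(f"subgroup size {size} outside {{1, ..., {d}}}")
    members = rng.choice(d, size=size, replace=False)
    return population.positions[members].mean(axis=0)


def handle_bounds(position: np.ndarray, params: CGOParams) -> np.ndarray:
    """Clip a point into the feasible box; idempotent."""
    lo, hi = params.bounds()
    return np.clip(np.asarray(position, float), lo, hi)


def generate_seeds(
    s_k: np.ndarray,
    g: np.ndarray,
    m_k: np.ndarray,
    params: CGOParams,
    rng: np.random.Generator,
) -> TriangleSeeds:
    """Generate the four candidate points of one temporary triangle.

    Each of P1-P3 uses independent ``alpha``, ``beta``, ``gamma`` draws
    (order per point: alpha, beta, gamma).  P4 perturbs a random non-empty
    subset of coordinates of ``S_k`` by independent uniform(0, 1) additions
    (each coordinate included with probability ``1/dim``, the subset
    redrawn while empty).  All four points are clipped into the box.
    """
    s_k = np.asarray(s_k, float)
    g = np.asarray(g, float)
    m_k = np.asarray(m_k, float)
    if not (s_k.shape == g.shape == m_k.shape == (params.dim,)):
        raise ValueError(
            "triangle vertices must all have shape "
            f"({params.dim},); got {s_k.shape}, {g.shape}, {m_k.shape}"
        )
    dom = np.asarray(params.beta_gamma_domain)
    alpha_size = params.dim if params.alpha_per_dimension else None

    def draws():
        alpha = sample_alpha(rng, size=alpha_size)
        beta = int(dom[rng.integers(2)])
        gamma = int(dom[rng.integers(2)])
        return alpha, beta, gamma

    a, b, c = draws()
    p1 = s_k + a * (b * g - c * m_k)
    a, b, c = draws()
    p2 = g + a * (b * s_k - c * m_k)
    a, b, c = draws()
    p3 = m_k + a * (b * s_k - c * g)

    while True:
        subset = rng.random(params.dim) < 1.0 / params.dim
        if subset.any():
            break
    p4 = s_k.copy()
    p4[subset] += rng.random(int(subset.sum()))

    return TriangleSeeds(
        p1=handle_bounds(p1, params),
        p2=handle_bounds(p2, params),
        p3=handle_bounds(p3, params),
        p4=handle_bounds(p4, params),
    )


def replace_if_better(
    population: SeedPopulation,
    candidates: Sequence[tuple[np.ndarray, float]],
) -> SeedPopulation:
    """Pool incumbents with candidates and keep the best ``D`` (elitist).

    Ties at the cut are broken in favour of earlier pool entries
    (incumbents before candidates, then lower row index), which a stable
    sort on the concatenated pool realizes.
    """
    d = population.size
    if not candidates:
        return population
    cand_pos = np.stack([np.asarray(p, float) for p, _ in candidates])
    cand_fit = np.array([float(f) for _, f in candidates])
    pool_pos = np.vstack([population.positions, cand_pos])
    pool_fit = np.concatenate([population.fitness, cand_fit])
    keep = np.argsort(pool_fit, kind="stable")[:d]
    positions = pool_pos[keep]
    fitness = pool_fit[keep]
    best = int(np.argmin(fitness))
    return SeedPopulation(
        positions=positions,
        fitness=fitness,
        global_best=positions[best].copy(),
        global_best_fitness=float(fitness[best]),
    )


def optimize(
    objective: Objective, params: CGOParams
) -> tuple[SeedPopulation, OptimizerTrace]:
    """Run CGO for the fixed iteration budget.

    Every iteration builds, for each seed ``S_k``, the temporary triangle
    ``(S_k, G, M_k)`` and its four candidate points (4D candidates per
    iteration), evaluates them, and applies one pool-and-truncate
    replacement.  ``G`` and the population are held fixed while one
    iteration's candidates are generated.  A single seeded generator
    drives all randomness, so equal seeds give bitwise-equal traces.
    """
    rng = np.random.default_rng(params.rng_seed)
    pop = initialize_population(params, objective, rng)
    evaluations = pop.size
    best_per_iter = np.empty(params.max_iterations)

    for it in range(params.max_iterations):
        cand_positions = []
        for k in range(pop.size):
            m_k = mean_group(pop, rng, size=params.mean_group_size)
            seeds = generate_seeds(
                pop.positions[k], pop.global_best, m_k, params, rng
            )
            cand_positions.append(seeds.as_array())
        cand_positions = np.vstack(cand_positions)
        cand_fitness = _evaluate_all(objective, cand_positions)
        evaluations += cand_positions.shape[0]
        pop = replace_if_better(
            pop, list(zip(cand_positions, cand_fitness))
        )
        best_per_iter[it] = pop.global_best_fitness

    trace = OptimizerTrace(
        best_fitness_per_iteration=best_per_iter,
        evaluations_used=evaluations,
        final_best_position=pop.global_best.copy(),
        initial_evaluations=pop.size,
    )
    return pop, trace


def random_search(
    objective: Objective, params: CGOParams
) -> tuple[SeedPopulation, OptimizerTrace]:
    """Uniform random search baseline with CGO's evaluation budget.

    Each iteration draws ``4 * D`` fresh uniform points (the same number of
    candidate evaluations CGO spends) and applies the same elitist
    replacement, making it a budget-matched pluggable alternative.
    """
    rng = np.random.default_rng(params.rng_seed)
    pop = initialize_population(params, objective, rng)
    evaluations = pop.size
    lo, hi = params.bounds()
    best_per_iter = np.empty(params.max_iterations)
    n_cand = 4 * pop.size
    for it in range(params.max_iterations):
        cand = rng.random((n_cand, params.dim)) * (hi - lo) + lo
        fit = _evaluate_all(objective, cand)
        evaluations += n_cand
        pop = replace_if_better(pop, list(zip(cand, fit)))
        best_per_iter[it] = pop.global_best_fitness
    trace = OptimizerTrace(
        best_fitness_per_iteration=best_per_iter,
        evaluations_used=evaluations,
        final_best_position=pop.global_best.copy(),
        initial_evaluations=pop.size,
    )
    return pop, trace


#: Registry of pluggable optimizers sharing the ``(objective, params)`` contract.
OPTIMIZERS: dict[str, Callable[[Objective, CGOParams], tuple[SeedPopulation, OptimizerTrace]]] = {
    "cgo": optimize,
    "random": random_search,
}


def chaos_game_sierpinski(
    vertices: np.ndarray,
    n_points: int,
    rng: np.random.Generator | None = None,
    burn_in: int = 20,
) -> np.ndarray:
    """Draw the Sierpinski attractor by the chaos game.

    Starting from the triangle centroid, repeatedly move halfway toward a
    uniformly chosen vertex; the first ``burn_in`` points are discarded so
    the returned cloud is the attractor rather than the seed transient.
    """
    if rng is None:
        rng = np.random.default_rng()
    v = np.asarray(vertices, float)
    if v.shape != (3, 2):
        raise ValueError("vertices must be three 2-D points")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    area2 = abs(
        (v[1, 0] - v[0, 0]) * (v[2, 1] - v[0, 1])
        - (v[2, 0] - v[0, 0]) * (v[1, 1] - v[0, 1])
    )
    scale = max(1.0, float(np.abs(v).max()))
    if area2 <= 1e-12 * scale * scale:
        raise ValueError("vertices are collinear")
    choices = rng.integers(0, 3, size=burn_in + n_points)
    pts = np.empty((n_points, 2))
    current = v.mean(axis=0)
    for i, c in enumerate(choices):
        current = (current + v[c]) / 2.0
        if i >= burn_in:
            pts[i - burn_in] = current
    return pts


def box_counting_dimension(
    points: np.ndarray, levels: Sequence[int] = (2, 3, 4, 5, 6, 7)
) -> float:
    """Box-counting (Minkowski) dimension estimate of a 2-D point cloud.

    The unit bounding box is divided into ``2^k x 2^k`` cells at each
    dyadic level ``k``; the slope of ``log(occupied cells)`` against
    ``log(2^k)`` is the dimension estimate.  For the Sierpinski triangle
    the theoretical value is ``log 3 / log 2 ~ 1.585``.
    """
    p = np.asarray(points, float)
    lo = p.min(axis=0)
    span = p.max(axis=0) - lo
    span[span == 0] = 1.0
    unit = (p - lo) / span
    logs_n, logs_c = [], []
    for k in levels:
        n = 2**k
        cells = np.minimum((unit * n).astype(int), n - 1)
        occupied = len({(int(a), int(b)) for a, b in cells})
        logs_n.append(np.log(n))
        logs_c.append(np.log(occupied))
    slope = np.polyfit(logs_n, logs_c, 1)[0]
    return float(slope)
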