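"""Chaotic sparrow search algorithm (CSSA), a bound-constrained minimizer.

The sparrow search algorithm evolves an N x D population under three roles
each iteration:

* discoverers — the best-fitness fraction, which either shrink their
  positions multiplicatively (``x <- x exp(-i / (alpha T))``) while the
  flock is safe (warning draw R2 below the safety value ST) or take a
  shared Gaussian step otherwise;
* joiners — the remainder; poorly ranked joiners (rank > N/2) jump near
  the worst position (``Q exp((x_worst - x) / i^2)``), the others forage
  around the current best;
* vigilantes — a random subset performing anti-predation moves relative to
  the worst position, with a guarded step
  ``K |x - x_worst| / ((f_i - f_w) + e)`` when already at the best fitness.

The chaotic refinement perturbs the incumbent best each iteration with a
logistic-map sequence (``rho_{k+1} = 4 rho_k (1 - rho_k)``) mapped into
the search box (``P = a + rho (b - a)``) and blended by the linear shrink
coefficient ``SC = (T - t + 1)/T``:  ``CL = (1 - SC) best + SC P``.  The
candidate replaces the best only on strict improvement, so the best-so-far
fitness history is non-increasing.

When coupled to the classifier, the objective is the validation
classification error rate in percent (:func:`fitness_error_rate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CSSAConfig",
    "SparrowPopulation",
    "Dimension",
    "OptimizeResult",
    "logistic_map_sequence",
    "chaotic_candidate",
    "fitness_error_rate",
    "update_discoverers",
    "update_joiners",
    "update_vigilantes",
    "optimize",
    "random_search",
    "tune_hyperparameters",
    "sphere",
    "rosenbrock",
    "rastrigin",
    "BENCHMARKS",
]

_FORBIDDEN_RHO = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class CSSAConfig:
    """CSSA settings.

    ``bounds`` is a (D, 2) array of per-dimension [a_d, b_d] boxes.  The
    safety value ST lives in [0.5, 1]; ``pd_frac`` / ``sd_frac`` set the
    discoverer and vigilante fractions; ``mu`` is pinned to 4, the fully
    chaotic logistic regime; ``rho1`` must avoid the map's rational fixed
    points; ``e`` stabilizes the vigilante denominator.
    """

    bounds: np.ndarray
    N: int = 20
    T: int = 100
    ST: float = 0.8
    pd_frac: float = 0.2
    sd_frac: float = 0.1
    e: float = 1e-8
    mu: float = 4.0
    rho1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("bounds must be (D, 2) with a_d < b_d")
        object.__setattr__(self, "bounds", b)
        if self.N < 4:
            raise ValueError("population size N must be >= 4")
        if self.T < 1:
            raise ValueError("iteration budget T must be >= 1")
        if not (0.5 <= self.ST <= 1.0):
            raise ValueError("safety value ST must lie in [0.5, 1]")
        if not (0.0 < self.pd_frac < 1.0 and 0.0 < self.sd_frac <= 1.0):
            raise ValueError("pd_frac and sd_frac must be fractions in (0, 1]")
        if self.e <= 0:
            raise ValueError("stabilizer e must be positive")
        if self.mu != 4.0:
            raise ValueError("the chaotic map control parameter mu is fixed at 4")
        _check_rho1(self.rho1)

    @property
    def D(self) -> int:
        return self.bounds.shape[0]

    @property
    def n_discoverers(self) -> int:
        return max(1, int(round(self.pd_frac * self.N)))

    @property
    def n_vigilantes(self) -> int:
        return max(1, int(round(self.sd_frac * self.N)))


def _check_rho1(rho1: float) -> None:
    if not (0.0 < rho1 < 1.0) or any(
        math.isclose(rho1, f, rel_tol=0.0, abs_tol=1e-12) for f in _FORBIDDEN_RHO
    ):
        raise ValueError(
            f"rho1 must lie in (0, 1) excluding {{0.25, 0.5, 0.75}}, got {rho1}"
        )


@dataclass
class SparrowPopulation:
    """Positions, fitness and best/worst bookkeeping for one CSSA run."""

    X: np.ndarray              # (N, D), always inside bounds
    fitness: np.ndarray        # (N,)
    x_best: np.ndarray
    f_g: float
    x_worst: np.ndarray
    f_w: float

    @classmethod
    def initialize(cls, objective: Callable, config: CSSAConfig,
                   rng: np.random.Generator,
                   initial_positions: np.ndarray | None = None) -> "SparrowPopulation":
        lo, hi = config.bounds[:, 0], config.bounds[:, 1]
        X = rng.uniform(lo, hi, size=(config.N, config.D))
        if initial_positions is not None:
            seeded = np.atleast_2d(np.asarray(initial_positions, dtype=float))
            X[: len(seeded)] = np.clip(seeded, lo, hi)
        fitness = np.array([objective(x) for x in X], dtype=float)
        pop = cls(X=X, fitness=fitness, x_best=X[0].copy(), f_g=float("inf"),
                  x_worst=X[0].copy(), f_w=-float("inf"))
        pop.refresh_extremes()
        return pop

    def refresh_extremes(self) -> None:
        ib, iw = int(np.argmin(self.fitness)), int(np.argmax(self.fitness))
        self.x_best = self.X[ib].copy()
        self.f_g = float(self.fitness[ib])
        self.x_worst = self.X[iw].copy()
        self.f_w = float(self.fitness[iw])


def _clip(X: np.ndarray, config: CSSAConfig) -> np.ndarray:
    return np.clip(X, config.bounds[:, 0], config.bounds[:, 1])


def update_discoverers(pop: SparrowPopulation, config: CSSAConfig,
                       rng: np.random.Generator, iteration: int) -> None:
    """Move the best-ranked pd_frac*N sparrows in place.

    One warning draw R2 per iteration: below ST every discoverer shrinks
    by exp(-i / (alpha T)) (alpha ~ U(0,1] per sparrow, i its 1-based
    rank); otherwise each takes a single N(0,1) step Q shared across
    dimensions.  Positions are clipped to the bounds.
    """
    order = np.argsort(pop.fitness, kind="stable")
    discoverers = order[: config.n_discoverers]
    r2 = rng.uniform()
    for rank, idx in enumerate(discoverers, start=1):
        if r2 < config.ST:
            alpha = 1.0 - rng.uniform(0.0, 1.0)  # U(0, 1], excludes 0
            pop.X[idx] = pop.X[idx] * math.exp(-rank / (alpha * config.T))
        else:
            q = rng.normal()
            pop.X[idx] = pop.X[idx] + q  # Q * L with L the all-ones row
    pop.X[discoverers] = _clip(pop.X[discoverers], config)
    _ = iteration  # rank, not the iteration counter, drives the decay


def update_joiners(pop: SparrowPopulation, config: CSSAConfig,
                   rng: np.random.Generator) -> None:
    """Move the non-discoverer sparrows in place.

    x_best refers to the position already updated this iteration (the
    best-fitness sparrow after the discoverer phase re-ranking by stored
    fitness).  Joiners ranked in the worse half jump to
    Q exp((x_worst - x)/i^2); the better half forage around x_best with a
    mean absolute-offset step re-drawn per dimension.
    """
    order = np.argsort(pop.fitness, kind="stable")
    joiners = order[config.n_discoverers:]
    best_idx = order[0]
    x_best = pop.X[best_idx]
    D = config.D
    for pos_in_order, idx in enumerate(joiners, start=config.n_discoverers + 1):
        i = pos_in_order  # 1-based fitness rank
        if i > config.N / 2:
            q = rng.normal()
            pop.X[idx] = q * np.exp((pop.x_worst - pop.X[idx]) / (i * i))
        else:
            step = np.mean(rng.uniform(-1.0, 1.0, size=D)
                           * np.abs(pop.X[idx] - x_best))
            pop.X[idx] = x_best + step
    pop.X[joiners] = _clip(pop.X[joiners], config)


def update_vigilantes(pop: SparrowPopulation, config: CSSAConfig,
                      rng: np.random.Generator) -> None:
    """Anti-predation moves for sd_frac*N randomly chosen sparrows.

    Sparrows not at the best fitness move relative to the worst position
    with a N(0,1) step length; the one(s) at the best fitness take the
    guarded step K |x - x_worst| / ((f_i - f_w) + e), K ~ U(-1, 1).
    """
    chosen = rng.choice(config.N, size=min(config.n_vigilantes, config.N),
                        replace=False)
    for idx in chosen:
        fi = pop.fitness[idx]
        if fi != pop.f_g:
            beta = rng.normal()
            pop.X[idx] = pop.x_worst + beta * np.abs(pop.X[idx] - pop.x_worst)
        else:
            k = rng.uniform(-1.0, 1.0)
            denom = (fi - pop.f_w) + config.e
            pop.X[idx] = pop.X[idx] + k * np.abs(pop.X[idx] - pop.x_worst) / denom
    pop.X[chosen] = _clip(pop.X[chosen], config)


def logistic_map_sequence(rho1: float, length: int) -> np.ndarray:
    """Logistic-map iterates rho_1..rho_length at mu = 4; all in [0, 1]."""
    _check_rho1(rho1)
    if length < 1:
        raise ValueError("length must be >= 1")
    seq = np.empty(length)
    seq[0] = rho1
    for k in range(1, length):
        seq[k] = 4.0 * seq[k - 1] * (1.0 - seq[k - 1])
    return seq


def chaotic_candidate(x_best: np.ndarray, rho_k: float, t: int,
                      config: CSSAConfig) -> np.ndarray:
    """Blend the best position with the chaotic point of the search box.

    P = a + rho (b - a) per dimension, SC = (T - t + 1)/T, and
    CL = (1 - SC) x_best + SC P — a convex combination, hence in bounds.
    At t = 1 the candidate is the pure chaotic point; at large T and
    t = T it stays close to the best.
    """
    if not (1 <= t <= config.T):
        raise ValueError(f"iteration t={t} outside [1, {config.T}]")
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    p = lo + rho_k * (hi - lo)
    sc = (config.T - t + 1) / config.T
    return (1.0 - sc) * np.asarray(x_best, dtype=float) + sc * p


def fitness_error_rate(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Classification error rate in percent: 100 * misclassified / total.

    Equals 100 minus the overall accuracy percentage; the quantity CSSA
    minimizes when tuning the classifier.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and truth must be equal-length and nonempty")
    return 100.0 * float(np.mean(pred != true))


@dataclass
class OptimizeResult:
    x_best: np.ndarray
    f_best: float
    history: np.ndarray        # best-so-far fitness after each iteration (length T)
    n_evaluations: int
    f_initial: float = float("inf")   # best fitness of the initial population
    mean_history: np.ndarray = field(default=None)


def optimize(objective: Callable, config: CSSAConfig,
             initial_positions: np.ndarray | None = None) -> OptimizeResult:
    """Run CSSA for T iterations; returns the best-ever position/fitness.

    Per iteration: discoverer, joiner and vigilante updates, one fitness
    evaluation per sparrow, then the chaotic candidate around the best,
    accepted only on strict improvement.  The best-so-far history is
    therefore non-increasing, and the run is deterministic given
    ``config.seed``.  ``initial_positions`` optionally pins the first
    population members (warm start).
    """
    rng = np.random.default_rng(config.seed)
    pop = SparrowPopulation.initialize(objective, config, rng, initial_positions)
    n_evals = config.N
    best_x = pop.x_best.copy()
    best_f = f_initial = pop.f_g
    history: list[float] = []
    mean_history: list[float] = []
    rho = logistic_map_sequence(config.rho1, config.T)
    for t in range(1, config.T + 1):
        update_discoverers(pop, config, rng, t)
        update_joiners(pop, config, rng)
        update_vigilantes(pop, config, rng)
        pop.fitness = np.array([objective(x) for x in pop.X], dtype=float)
        n_evals += config.N
        pop.refresh_extremes()
        if pop.f_g < best_f:
            best_f = pop.f_g
            best_x = pop.x_best.copy()
        cl = chaotic_candidate(best_x, rho[t - 1], t, config)
        f_cl = float(objective(cl))
        n_evals += 1
        if f_cl < best_f:
            best_f = f_cl
            best_x = cl.copy()
            ib = int(np.argmax(pop.fitness))
            pop.X[ib] = cl
            pop.fitness[ib] = f_cl
            pop.refresh_extremes()
        history.append(best_f)
        mean_history.append(float(pop.fitness.mean()))
    return OptimizeResult(x_best=best_x, f_best=best_f,
                          history=np.array(history), n_evaluations=n_evals,
                          f_initial=f_initial, mean_history=np.array(mean_history))


def random_search(objective: Callable, bounds: np.ndarray, n_evaluations: int,
                  seed: int = 0) -> OptimizeResult:
    """Uniform random search baseline at a matched evaluation budget."""
    rng = np.random.default_rng(seed)
    b = np.atleast_2d(np.asarray(bounds, dtype=float))
    best_x, best_f, history = None, float("inf"), []
    for _ in range(n_evaluations):
        x = rng.uniform(b[:, 0], b[:, 1])
        f = float(objective(x))
        if f < best_f:
            best_f, best_x = f, x
        history.append(best_f)
    return OptimizeResult(x_best=best_x, f_best=best_f,
                          history=np.array(history), n_evaluations=n_evaluations)


# ---- hyperparameter space ------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    """One tunable hyperparameter: continuous, integer or log-scale bounds."""

    name: str
    low: float
    high: float
    kind: str = "continuous"   # "continuous" | "integer" | "log"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "log"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.low > self.high:
            raise ValueError(f"{self.name}: low must be <= high")
        if self.kind == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log-scale bounds must be positive")

    @property
    def position_bounds(self) -> tuple[float, float]:
        if self.kind == "log":
            return (math.log10(self.low), math.log10(self.high))
        return (self.low, self.high)

    def decode(self, value: float):
        if self.kind == "log":
            return float(10.0 ** value)
        if self.kind == "integer":
            return int(np.clip(round(value), self.low, self.high))
        return float(value)


def decode_position(position: np.ndarray, space: Sequence[Dimension]) -> dict:
    return {d.name: d.decode(v) for d, v in zip(space, position)}


def tune_hyperparameters(space: Sequence[Dimension], objective: Callable[[dict], float],
                         config_kwargs: dict | None = None, seed: int = 0,
                         warm_start: dict | None = None):
    """Minimize an objective over a named hyperparameter space with CSSA.

    ``objective`` receives a decoded {name: value} dict (typically
    returning the validation error rate in percent).  ``warm_start``
    seeds one population member at a known-good configuration so the
    tuned result can never be worse than it under the same objective.
    Returns (best hyperparameter dict, OptimizeResult).
    """
    space = list(space)
    if not space:
        raise ValueError("hyperparameter space must not be empty")
    eps = 1e-9
    bounds = np.array([
        (lo, hi if hi > lo else lo + eps)
        for lo, hi in (d.position_bounds for d in space)
    ])
    kwargs = dict(N=8, T=5, seed=seed)
    kwargs.update(config_kwargs or {})
    config = CSSAConfig(bounds=bounds, **kwargs)

    def wrapped(position: np.ndarray) -> float:
        return float(objective(decode_position(position, space)))

    start = None
    if warm_start is not None:
        start = np.array([
            math.log10(warm_start[d.name]) if d.kind == "log" else float(warm_start[d.name])
            for d in space
        ])
    result = optimize(wrapped, config, initial_positions=start)
    return decode_position(result.x_best, space), result


# ---- benchmark objectives ------------------------------------------------

def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


BENCHMARKS = {"sphere": sphere, "rosenbrock": rosenbrock, "rastrigin": rastrigin}
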