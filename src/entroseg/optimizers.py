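"""Population-based maximizers for multilevel thresholding.

Three search algorithms operate on continuous agent positions in
``[1, 255]^K`` that are decoded to integer threshold vectors for every
objective evaluation:

* ``woa`` — the whale optimization algorithm: encircling the best-so-far
  solution, a logarithmic-spiral move around it, and a random-agent search
  move, gated by the linearly decaying coefficient ``a`` (2 -> 0).
* ``de`` — differential evolution (rand/1/bin) with greedy selection.
* ``woa_de`` — the hybrid: each generation, agents whose fitness exceeds the
  population mean take a DE step (exploitation / local refinement) while the
  rest take a WOA step (exploration).  This keeps a global-search pressure
  alive after ``a`` drops below 1, when plain WOA can only exploit.

Generations are synchronous: the population mean fitness, the best-so-far
attractor and the DE partner pool are all snapshotted before any agent moves,
so results are independent of agent ordering and fully reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, Optional, Tuple

import numpy as np

__all__ = [
    "OptimizerConfig",
    "OptimizerResult",
    "a_schedule",
    "decode_thresholds",
    "woa_move",
    "de_mutation",
    "de_crossover",
    "de_selection",
    "optimize",
    "ALGORITHMS",
]

ALGORITHMS = ("woa_de", "woa", "de")


@dataclass(frozen=True)
class OptimizerConfig:
    """Search parameters shared by all three algorithms.

    Defaults follow the standard benchmark protocol for this method family:
    30 agents, 500 generations, DE crossover rate 0.9 and scaling factor 0.5,
    spiral shape constant b = 1, positions bounded to [1, 255].
    """

    n_agents: int = 30
    max_iter: int = 500
    crossover_rate: float = 0.9
    scale_factor: float = 0.5
    spiral_b: float = 1.0
    seed: int = 0
    lower: float = 1.0
    upper: float = 255.0

    def __post_init__(self) -> None:
        if self.n_agents < 4:
            raise ValueError("n_agents must be >= 4 (DE needs 3 partners plus target)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")

    def with_seed(self, seed: int) -> "OptimizerConfig":
        return replace(self, seed=seed)


@dataclass
class OptimizerResult:
    """Best solution found plus the per-generation best-so-far trace."""

    best_thresholds: np.ndarray
    best_fitness: float
    history: np.ndarray  # length max_iter, non-decreasing
    evaluations: int
    n_woa_moves: int = 0
    n_de_moves: int = 0


def a_schedule(t: int, max_iter: int) -> float:
    """Linearly decaying coefficient ``a = 2 - 2 t / max_iter``.

    ``a`` controls the amplitude coefficient ``A = 2 a r - a`` (r uniform in
    [0,1]), so ``|A| <= a``; once ``a`` drops below 1 (at t = max_iter/2) the
    random-search branch can no longer fire.
    """
    if not 0 <= t <= max_iter:
        raise ValueError("iteration index out of range")
    return 2.0 - 2.0 * t / max_iter


def decode_thresholds(position: np.ndarray, lower: float = 1.0, upper: float = 255.0) -> np.ndarray:
    """Decode a continuous position into a valid threshold vector.

    Coordinates are sorted, rounded to the nearest integer and clipped to
    [1, 255]; duplicate values are repaired by pushing collided thresholds
    upward, spilling downward where 255 is hit.
    """
    vals = np.sort(np.asarray(position, dtype=float))
    vals = np.clip(np.floor(vals + 0.5), max(1.0, lower), min(255.0, upper)).astype(np.int64)
    k = vals.size
    for i in range(1, k):
        if vals[i] <= vals[i - 1]:
            vals[i] = vals[i - 1] + 1
    # spill back down if the upward pass ran past 255
    for i in range(k - 1, -1, -1):
        cap = 255 - (k - 1 - i)
        if vals[i] > cap:
            vals[i] = cap
    for i in range(1, k):
        if vals[i] <= vals[i - 1]:
            vals[i] = vals[i - 1] + 1
    return vals


def woa_move(
    x: np.ndarray,
    x_star: np.ndarray,
    x_rand: np.ndarray,
    a: float,
    rng: np.random.Generator,
    b: float = 1.0,
    lower: float = 1.0,
    upper: float = 255.0,
) -> np.ndarray:
    """One whale position update; the branch is drawn internally.

    With probability 1/2 (p >= 0.5) the spiral move
    ``x' = D' e^{b l} cos(2 pi l) + x*`` fires with ``l`` uniform in [-1, 1]
    and ``D' = |x* - x|``.  Otherwise ``A = 2 a r - a`` and ``C = 2 r'`` are
    drawn; if ``|A| < 1`` the agent encircles the best-so-far solution
    (``x' = x* - A |C x* - x|``), else it searches around a random agent
    (``x' = x_r - A |C x_r - x|``).  The result is clamped to the bounds.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != np.shape(x_star) or x.shape != np.shape(x_rand):
        raise ValueError("position dimension mismatch")
    if not 0.0 <= a <= 2.0:
        raise ValueError("a must lie in [0, 2]")
    p = rng.random()
    if p >= 0.5:
        l = rng.uniform(-1.0, 1.0)
        d = np.abs(x_star - x)
        new = d * np.exp(b * l) * np.cos(2.0 * np.pi * l) + x_star
    else:
        A = 2.0 * a * rng.random() - a
        C = 2.0 * rng.random()
        if abs(A) < 1.0:
            new = x_star - A * np.abs(C * x_star - x)
        else:
            new = x_rand - A * np.abs(C * x_rand - x)
    return np.clip(new, lower, upper)


def de_mutation(
    x_r1: np.ndarray,
    x_r2: np.ndarray,
    x_r3: np.ndarray,
    scale_factor: float,
    lower: float = 1.0,
    upper: float = 255.0,
) -> np.ndarray:
    """rand/1 mutant ``m = x_r1 + SF (x_r2 - x_r3)``, clamped to bounds."""
    m = np.asarray(x_r1, dtype=float) + scale_factor * (
        np.asarray(x_r2, dtype=float) - np.asarray(x_r3, dtype=float)
    )
    return np.clip(m, lower, upper)


def de_crossover(
    x: np.ndarray, m: np.ndarray, crossover_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover: each coordinate takes the mutant iff rand <= CR."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise ValueError("position dimension mismatch")
    draws = rng.random(x.shape)
    return np.where(draws <= crossover_rate, m, x)


def de_selection(
    x: np.ndarray, trial: np.ndarray, f: Callable[[np.ndarray], float]
) -> np.ndarray:
    """Greedy selection under maximization: keep the trial iff strictly better."""
    return np.asarray(trial) if f(trial) > f(x) else np.asarray(x)


class _CachedDecoder:
    """Decode positions and memoize objective values by integer threshold tuple.

    Caching never changes results (decoded tuples map to a deterministic
    fitness); the evaluation counter tracks *requests*, so it is independent
    of cache hits.
    """

    def __init__(self, objective, lower: float, upper: float):
        self.objective = objective
        self.lower = lower
        self.upper = upper
        self.cache: Dict[Tuple[int, ...], float] = {}
        self.evaluations = 0

    def __call__(self, position: np.ndarray) -> Tuple[np.ndarray, float]:
        th = decode_thresholds(position, self.lower, self.upper)
        key = tuple(int(v) for v in th)
        self.evaluations += 1
        if key not in self.cache:
            self.cache[key] = float(self.objective(th))
        return th, self.cache[key]


def optimize(
    objective: Callable[[np.ndarray], float],
    K: int,
    config: Optional[OptimizerConfig] = None,
    algorithm: str = "woa_de",
) -> OptimizerResult:
    """Maximize ``objective`` over K-threshold vectors.

    Parameters
    ----------
    objective : callable
        Maps a valid integer threshold vector to a fitness value (maximized).
    K : int
        Number of thresholds (search dimension).
    config : OptimizerConfig, optional
        Search parameters; defaults are used when omitted.
    algorithm : {"woa_de", "woa", "de"}
        ``woa_de`` routes above-mean-fitness agents through DE and the rest
        through WOA; ``woa`` and ``de`` are the pure baselines.

    Returns
    -------
    OptimizerResult
        Best-ever decoded thresholds, fitness, the per-generation
        best-so-far history (non-decreasing), and move/evaluation counters.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    cfg = config or OptimizerConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_agents
    evaluate = _CachedDecoder(objective, cfg.lower, cfg.upper)

    X = rng.uniform(cfg.lower, cfg.upper, size=(n, K))
    fitness = np.empty(n)
    best_fitness = -np.inf
    best_thresholds = None
    best_position = None
    for i in range(n):
        th, fitness[i] = evaluate(X[i])
        if fitness[i] > best_fitness:
            best_fitness, best_thresholds, best_position = fitness[i], th, X[i].copy()

    history = np.empty(cfg.max_iter)
    n_woa = n_de = 0

    for t in range(cfg.max_iter):
        a = a_schedule(t, cfg.max_iter)
        f_bar = float(fitness.mean())
        X_snap = X.copy()
        fit_snap = fitness.copy()
        x_star = best_position.copy()  # best-so-far attractor, fixed per generation
        for i in range(n):
            if algorithm == "de":
                de_branch = True
            elif algorithm == "woa":
                de_branch = False
            else:
                de_branch = fit_snap[i] > f_bar
            if de_branch:
                n_de += 1
                others = np.delete(np.arange(n), i)
                r1, r2, r3 = rng.choice(others, size=3, replace=False)
                mutant = de_mutation(
                    X_snap[r1], X_snap[r2], X_snap[r3], cfg.scale_factor, cfg.lower, cfg.upper
                )
                trial = de_crossover(X_snap[i], mutant, cfg.crossover_rate, rng)
                th, f_trial = evaluate(trial)
                if f_trial > fit_snap[i]:  # greedy selection, ties keep the target
                    X[i], fitness[i] = trial, f_trial
                new_pos, new_fit, new_th = trial, f_trial, th
            else:
                n_woa += 1
                i_rand = int(rng.integers(n))
                new = woa_move(
                    X_snap[i], x_star, X_snap[i_rand], a, rng,
                    b=cfg.spiral_b, lower=cfg.lower, upper=cfg.upper,
                )
                th, f_new = evaluate(new)
                X[i], fitness[i] = new, f_new
                new_pos, new_fit, new_th = new, f_new, th
            if new_fit > best_fitness:
                best_fitness = float(new_fit)
                best_thresholds = new_th
                best_position = np.asarray(new_pos, dtype=float).copy()
        history[t] = best_fitness

    return OptimizerResult(
        best_thresholds=np.asarray(best_thresholds),
        best_fitness=float(best_fitness),
        history=history,
        evaluations=evaluate.evaluations,
        n_woa_moves=n_woa,
        n_de_moves=n_de,
    )
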