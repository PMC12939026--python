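"""Bounded single-objective genetic algorithm for surrogate setpoints.

Minimization convention throughout: to maximize permeate flux the fitness
is the negative predicted flux, so reported best-fitness values for a
flux run are negative numbers.  The operator set is tournament selection
(size 2), blend (BLX-0.5) crossover, and bound-respecting Gaussian
mutation with per-generation step decay; elites are copied unchanged, so
the best-fitness trajectory is non-increasing by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GAConfig", "GAResult", "run_ga", "optimize_response"]


@dataclass
class GAConfig:
    population_size: int = 120
    generations: int = 50
    elite_fraction: float = 0.05
    stall_generations: int = 8
    bounds: tuple[tuple[float, float], ...] = ((50.0, 200.0), (20.0, 40.0))
    seed: int = 0
    crossover_fraction: float = 0.8
    blend_alpha: float = 0.5
    tournament_size: int = 2
    mutation_scale: float = 0.15  # initial sigma as a fraction of each span
    stall_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        if not (0.0 <= self.elite_fraction < 1.0):
            raise ValueError("elite_fraction must lie in [0, 1)")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and hi > lo):
                raise ValueError(f"invalid bound ({lo}, {hi})")


@dataclass
class GAResult:
    best_x: np.ndarray
    best_fitness: float
    best_history: list[float] = field(default_factory=list)
    mean_history: list[float] = field(default_factory=list)
    generations: int = 0
    termination: str = "generations"
    n_nonfinite: int = 0


def _evaluate(fitness, pop: np.ndarray) -> tuple[np.ndarray, int]:
    vals = np.empty(len(pop))
    bad = 0
    for i, x in enumerate(pop):
        v = fitness(x)
        if not np.isfinite(v):
            v = np.inf
            bad += 1
        vals[i] = v
    return vals, bad


def run_ga(fitness, config: GAConfig) -> GAResult:
    """Minimize ``fitness`` over the configured box.

    Candidates outside bounds never occur: crossover results are clamped
    and mutations are resampled until feasible (clamping as a last
    resort).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    dim = len(config.bounds)
    npop = config.population_size
    n_elite = max(1, int(round(config.elite_fraction * npop)))

    pop = lo + rng.uniform(size=(npop, dim)) * span
    vals, bad_total = _evaluate(fitness, pop)

    result = GAResult(best_x=pop[np.argmin(vals)].copy(), best_fitness=float(vals.min()))
    stall = 0

    def tournament() -> np.ndarray:
        idx = rng.integers(npop, size=config.tournament_size)
        return pop[idx[np.argmin(vals[idx])]]

    gen = 0
    for gen in range(1, config.generations + 1):
        order = np.argsort(vals)
        sigma = config.mutation_scale * span * (1.0 - (gen - 1) / config.generations)
        sigma = np.maximum(sigma, 1e-3 * span)
        new_pop = [pop[i].copy() for i in order[:n_elite]]
        n_children = npop - n_elite
        n_xover = int(round(config.crossover_fraction * n_children))
        for _ in range(n_xover):
            p1, p2 = tournament(), tournament()
            d = p2 - p1
            u = rng.uniform(-config.blend_alpha, 1.0 + config.blend_alpha, size=dim)
            child = np.clip(p1 + u * d, lo, hi)
            new_pop.append(child)
        for _ in range(n_children - n_xover):
            parent = tournament()
            child = None
            for _attempt in range(10):
                cand = parent + rng.normal(0.0, sigma)
                if np.all(cand >= lo) and np.all(cand <= hi):
                    child = cand
                    break
            if child is None:
                child = np.clip(parent + rng.normal(0.0, sigma), lo, hi)
            new_pop.append(child)
        pop = np.array(new_pop)
        vals, bad = _evaluate(fitness, pop)
        bad_total += bad

        gen_best = float(vals.min())
        improvement = result.best_fitness - gen_best
        if gen_best < result.best_fitness:
            result.best_fitness = gen_best
            result.best_x = pop[np.argmin(vals)].copy()
        result.best_history.append(result.best_fitness)
        finite = vals[np.isfinite(vals)]
        result.mean_history.append(float(finite.mean()) if len(finite) else np.inf)
        if improvement < config.stall_tol:
            stall += 1
            if stall >= config.stall_generations:
                result.termination = "stall"
                break
        else:
            stall = 0
    result.generations = gen
    result.n_nonfinite = bad_total
    if bad_total:
        warnings.warn(f"{bad_total} candidate(s) returned non-finite fitness")
    return result


def optimize_response(model, response: str, direction: str, config: GAConfig) -> GAResult:
    """GA search on a fitted surrogate (quadratic surface or MLP).

    ``direction='max'`` wraps the prediction as fitness = -prediction, so
    the reported best fitness follows the minimization convention
    (negative for a flux-maximization run).
    """
    from cocoflux.ann import MLPSurrogate
    from cocoflux.rsm import QuadraticSurface

    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    sign = -1.0 if direction == "max" else 1.0

    if isinstance(model, QuadraticSurface):
        if response != model.response_name:
            raise KeyError(
                f"surface models {model.response_name!r}, not {response!r}"
            )

        def fitness(x):
            v, _ = model.predict_actual(x[0], x[1])
            return sign * v

    elif isinstance(model, MLPSurrogate):
        try:
            k = model.response_names.index(response)
        except ValueError:
            raise KeyError(f"unknown response {response!r}") from None

        def fitness(x):
            return sign * model.predict(float(x[0]), float(x[1]))[k]

    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warnings at box edges
        return run_ga(fitness, config)
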