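"""Bound-constrained single-objective metaheuristics over the input box.

Four population algorithms share one problem/result contract and are used
to maximize a fitted trait surrogate over the culture-input box (four light
channels in [0, 100] μmol/m²/s, sucrose in [1, 6] % w/v):

* **GA** — real-coded genetic algorithm: roulette-wheel selection on
  shifted-positive fitness, two-point crossover, uniform resampling
  mutation, elitism.
* **BBO** — biogeography-based optimization: rank-based emigration and
  immigration rates, roulette choice of the donor habitat, blended
  migration ``SIVᵢ ← SIVᵢ + α(SIVⱼ − SIVᵢ)``, Gaussian mutation, elitism.
* **ISA** — interior search algorithm: a mirror-search/composition split
  controlled by a threshold α growing linearly 0.1 → 0.9 over iterations, a
  local random walk of the incumbent with scale 0.01·(UB−LB), and greedy
  acceptance.
* **SOS** — symbiotic organisms search: mutualism, commensalism and
  parasitism phases, all greedily accepted; no algorithm-specific tuning
  parameters beyond population and generations.

Every candidate is clipped to the box after each move, and the incumbent
trajectory reported in ``history`` is monotone non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd


class OptimizerError(ValueError):
    pass


@dataclass(frozen=True)
class Problem:
    """A maximization problem: batch objective + per-dimension bounds."""

    objective: Callable[[np.ndarray], np.ndarray]
    bounds: np.ndarray  # (d, 2)

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise OptimizerError("bounds must have shape (d, 2)")
        if np.any(b[:, 0] >= b[:, 1]):
            raise OptimizerError("each lower bound must be < upper bound")
        object.__setattr__(self, "bounds", b)

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    @property
    def lb(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def ub(self) -> np.ndarray:
        return self.bounds[:, 1]

    @classmethod
    def from_model(cls, model, bounds) -> "Problem":
        """Maximize a fitted :class:`~cultivopt.models.SurrogateModel`."""
        return cls(objective=lambda X: model.predict(X), bounds=bounds)


@dataclass(frozen=True)
class GAConfig:
    population: int = 200
    generations: int = 1000
    seed: int = 0
    mutation_rate: float = 0.05
    crossover_fraction: float = 0.6
    n_elites: int = 2


@dataclass(frozen=True)
class BBOConfig:
    population: int = 200
    generations: int = 1000
    seed: int = 0
    mutation_rate: float = 0.05
    alpha: float = 1.0
    E: float = 1.0
    I: float = 1.0
    mutation_scale: float = 0.1  # Gaussian sd as a fraction of (UB − LB)
    n_elites: int = 2
    as_printed: bool = False  # migration with the (divergent) plus sign


@dataclass(frozen=True)
class ISAConfig:
    population: int = 200
    generations: int = 1000
    seed: int = 0
    alpha_start: float = 0.1
    alpha_end: float = 0.9
    walk_scale: float = 0.01  # λ_w = walk_scale · (UB − LB)


@dataclass(frozen=True)
class SOSConfig:
    population: int = 200
    generations: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class OptimizationResult:
    algorithm: str
    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # incumbent best_f per generation
    evaluations: int
    seed: int


class _Tracker:
    """Counts evaluations, checks finiteness, tracks the incumbent."""

    def __init__(self, problem: Problem):
        self.problem = problem
        self.evaluations = 0
        self.best_x: np.ndarray | None = None
        self.best_f = -np.inf

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        f = np.asarray(self.problem.objective(X), dtype=float).ravel()
        self.evaluations += X.shape[0]
        if not np.isfinite(f).all():
            bad = X[~np.isfinite(f)][0]
            raise OptimizerError(f"non-finite objective at {bad}")
        i = int(np.argmax(f))
        if f[i] > self.best_f:
            self.best_f = float(f[i])
            self.best_x = X[i].copy()
        return f


def _validate(cfg) -> None:
    if cfg.population < 2:
        raise OptimizerError("population must be >= 2")
    if cfg.generations < 1:
        raise OptimizerError("generations must be >= 1")
    for name in ("mutation_rate", "crossover_fraction"):
        if hasattr(cfg, name) and not 0.0 <= getattr(cfg, name) <= 1.0:
            raise OptimizerError(f"{name} must lie in [0, 1]")


def _init_pop(problem: Problem, n: int, rng) -> np.ndarray:
    span = problem.ub - problem.lb
    return problem.lb + span * rng.random((n, problem.dim))


def _clip(X: np.ndarray, problem: Problem) -> np.ndarray:
    return np.clip(X, problem.lb, problem.ub)


def _roulette_probs(fit: np.ndarray) -> np.ndarray:
    shifted = fit - fit.min() + 1e-12
    return shifted / shifted.sum()


def _result(name, tracker, history, cfg) -> OptimizationResult:
    return OptimizationResult(
        algorithm=name,
        best_x=tracker.best_x,
        best_f=tracker.best_f,
        history=np.array(history),
        evaluations=tracker.evaluations,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# GA


def optimize_ga(problem: Problem, config: GAConfig = GAConfig()) -> OptimizationResult:
    _validate(config)
    rng = np.random.default_rng(config.seed)
    n, d = config.population, problem.dim
    f = _Tracker(problem)
    pop = _init_pop(problem, n, rng)
    fit = f(pop)
    history = []
    for _ in range(config.generations):
        probs = _roulette_probs(fit)
        parents = pop[rng.choice(n, size=n, p=probs)]
        children = parents.copy()
        for a in range(0, n - 1, 2):
            if rng.random() < config.crossover_fraction and d >= 2:
                if d > 2:
                    c1, c2 = np.sort(rng.choice(np.arange(1, d), 2, replace=False))
                else:
                    c1, c2 = 1, 1
                seg = children[a, c1:c2].copy()
                children[a, c1:c2] = children[a + 1, c1:c2]
                children[a + 1, c1:c2] = seg
        mut = rng.random((n, d)) < config.mutation_rate
        resampled = problem.lb + (problem.ub - problem.lb) * rng.random((n, d))
        children[mut] = resampled[mut]
        children = _clip(children, problem)
        child_fit = f(children)
        # elitism: best incumbents survive into the new generation
        elite_idx = np.argsort(fit)[-config.n_elites:]
        worst_idx = np.argsort(child_fit)[: config.n_elites]
        children[worst_idx] = pop[elite_idx]
        child_fit[worst_idx] = fit[elite_idx]
        pop, fit = children, child_fit
        history.append(f.best_f)
    return _result("ga", f, history, config)


# ---------------------------------------------------------------------------
# BBO


def optimize_bbo(problem: Problem, config: BBOConfig = BBOConfig()) -> OptimizationResult:
    _validate(config)
    rng = np.random.default_rng(config.seed)
    n, d = config.population, problem.dim
    f = _Tracker(problem)
    pop = _init_pop(problem, n, rng)
    fit = f(pop)
    span = problem.ub - problem.lb
    sign = 1.0 if config.as_printed else -1.0
    history = []
    for _ in range(config.generations):
        # rank-based species counts: best habitat is fullest
        order = np.argsort(-fit)
        s = np.empty(n)
        s[order] = 1.0 - np.arange(n) / (n - 1)  # arithmetic progression 1→0
        mu = config.E * s
        lam = config.I * (1.0 - s)
        donors_p = mu / mu.sum()
        immigrate = rng.random((n, d)) < lam[:, None]
        donor_idx = rng.choice(n, size=(n, d), p=donors_p)
        donor_vals = pop[donor_idx, np.arange(d)[None, :]]
        # blended migration; `as_printed` flips to the divergent plus sign
        migrated = pop + config.alpha * (donor_vals + sign * pop)
        new_pop = np.where(immigrate, migrated, pop)
        mut = rng.random((n, d)) < config.mutation_rate
        noise = rng.normal(scale=config.mutation_scale * span, size=(n, d))
        new_pop = np.where(mut, new_pop + noise, new_pop)
        new_pop = _clip(new_pop, problem)
        new_fit = f(new_pop)
        elite_idx = np.argsort(fit)[-config.n_elites:]
        worst_idx = np.argsort(new_fit)[: config.n_elites]
        new_pop[worst_idx] = pop[elite_idx]
        new_fit[worst_idx] = fit[elite_idx]
        pop, fit = new_pop, new_fit
        history.append(f.best_f)
    return _result("bbo", f, history, config)


# ---------------------------------------------------------------------------
# ISA


def isa_alpha(t: int, generations: int, start: float = 0.1, end: float = 0.9) -> float:
    """Linear mirror-threshold schedule; reaches ``end`` at the last iteration."""
    if generations <= 1:
        return end
    return start + (end - start) * t / (generations - 1)


def optimize_isa(problem: Problem, config: ISAConfig = ISAConfig()) -> OptimizationResult:
    _validate(config)
    rng = np.random.default_rng(config.seed)
    n, d = config.population, problem.dim
    f = _Tracker(problem)
    pop = _init_pop(problem, n, rng)
    fit = f(pop)
    span = problem.ub - problem.lb
    lam_w = config.walk_scale * span
    T = config.generations
    history = []
    for t in range(T):
        alpha = isa_alpha(t, T, config.alpha_start, config.alpha_end)
        gb = int(np.argmax(fit))
        x_gb = pop[gb]
        cand = np.empty_like(pop)
        # incumbent: local random walk
        cand[gb] = x_gb + rng.standard_normal(d) * lam_w
        r1 = rng.random(n)
        for i in range(n):
            if i == gb:
                continue
            if r1[i] <= alpha:  # mirror search
                r3 = rng.random()
                x_m = r3 * pop[i] + (1.0 - r3) * x_gb
                cand[i] = 2.0 * x_m - pop[i]
            else:  # composition: uniform resampling in bounds
                cand[i] = problem.lb + span * rng.random(d)
        cand = _clip(cand, problem)
        cand_fit = f(cand)
        accept = cand_fit > fit
        pop = np.where(accept[:, None], cand, pop)
        fit = np.where(accept, cand_fit, fit)
        history.append(f.best_f)
    return _result("isa", f, history, config)


# ---------------------------------------------------------------------------
# SOS


def optimize_sos(problem: Problem, config: SOSConfig = SOSConfig()) -> OptimizationResult:
    _validate(config)
    rng = np.random.default_rng(config.seed)
    n, d = config.population, problem.dim
    f = _Tracker(problem)
    pop = _init_pop(problem, n, rng)
    fit = f(pop)
    span = problem.ub - problem.lb
    history = []

    def other(i):
        j = int(rng.integers(n - 1))
        return j + (j >= i)

    for _ in range(config.generations):
        for i in range(n):
            best = pop[int(np.argmax(fit))]
            # mutualism
            j = other(i)
            mv = 0.5 * (pop[i] + pop[j])
            bf1, bf2 = rng.integers(1, 3, size=2)
            xi_new = _clip(pop[i] + rng.random(d) * (best - mv * bf1), problem)
            xj_new = _clip(pop[j] + rng.random(d) * (best - mv * bf2), problem)
            fi, fj = f(np.vstack([xi_new, xj_new]))
            if fi > fit[i]:
                pop[i], fit[i] = xi_new, fi
            if fj > fit[j]:
                pop[j], fit[j] = xj_new, fj
            # commensalism
            best = pop[int(np.argmax(fit))]
            j = other(i)
            xi_new = _clip(pop[i] + rng.random(d) * (best - pop[j]), problem)
            fi = f(xi_new)[0]
            if fi > fit[i]:
                pop[i], fit[i] = xi_new, fi
            # parasitism
            j = other(i)
            pv = pop[i].copy()
            n_dims = int(rng.integers(1, d + 1))
            dims = rng.choice(d, size=n_dims, replace=False)
            pv[dims] = problem.lb[dims] + span[dims] * rng.random(n_dims)
            fp = f(pv)[0]
            if fp > fit[j]:
                pop[j], fit[j] = pv, fp
        history.append(f.best_f)
    return _result("sos", f, history, config)


# ---------------------------------------------------------------------------
# Runner


_ALGORITHMS = {
    "ga": (optimize_ga, GAConfig),
    "bbo": (optimize_bbo, BBOConfig),
    "isa": (optimize_isa, ISAConfig),
    "sos": (optimize_sos, SOSConfig),
}


def default_configs(
    population: int = 200, generations: int = 1000, seed: int = 0
) -> dict:
    """One config per algorithm at a shared population/budget/seed."""
    return {
        name: cfg_cls(population=population, generations=generations, seed=seed)
        for name, (_, cfg_cls) in _ALGORITHMS.items()
    }


def optimize_all(
    problem: Problem, configs: Mapping | None = None
) -> dict[str, OptimizationResult]:
    """Run all four algorithms; individual failures are recorded, not fatal."""
    configs = dict(configs or default_configs())
    results: dict[str, OptimizationResult] = {}
    errors: dict[str, Exception] = {}
    for name, cfg in configs.items():
        fn, _ = _ALGORITHMS[name]
        try:
            results[name] = fn(problem, cfg)
        except OptimizerError as exc:  # pragma: no cover - defensive
            errors[name] = exc
    if errors and not results:
        raise OptimizerError(f"all algorithms failed: {errors}")
    return results


def best_f_spread(results: Mapping[str, OptimizationResult]) -> float:
    """Relative spread of best objective values across algorithms."""
    vals = np.array([r.best_f for r in results.values()])
    scale = max(abs(float(vals.mean())), 1e-12)
    return float((vals.max() - vals.min()) / scale)


def results_table(
    results: Mapping[str, OptimizationResult],
    input_names: tuple[str, ...] | None = None,
    trait: str = "",
) -> pd.DataFrame:
    """Tabulate per-algorithm optima (one row per algorithm)."""
    rows = []
    for name, r in results.items():
        row = {"trait": trait, "algorithm": name}
        names = input_names or [f"x{i}" for i in range(r.best_x.size)]
        row.update(dict(zip(names, r.best_x)))
        row["best_f"] = r.best_f
        row["evaluations"] = r.evaluations
        row["seed"] = r.seed
        rows.append(row)
    return pd.DataFrame(rows)
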