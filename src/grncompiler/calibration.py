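"""Model calibration by a genetic algorithm minimizing chi-square.

The objective is a sum over fitted species of masked chi-square terms

    chi2_s = sum_{i in mask_s} ((pred_s(x_i) - obs_s(x_i)) / sd_s(x_i))**2,

reported alongside the reduced (penalized) chi-square
``chi2 / (N_masked - n_params)``.  Position masks restrict each species to
the axis range the model is expected to describe (terminal embryo regions
are under the control of regulators outside the network and can be
excluded).

Optimization is a generational genetic algorithm over log10-transformed
parameters (rates are positive and scale-free): tournament selection,
blend crossover, Gaussian mutation in log space, elitism, and a fixed seed
for bit-reproducible runs.  Individuals whose forward simulation fails
score +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .spatial import SpatialField, SpatialProfile

__all__ = [
    "chi_square",
    "FitProblem",
    "GAConfig",
    "FitResult",
    "ga_minimize",
]


def chi_square(
    predicted: SpatialProfile,
    observed: SpatialProfile,
    mask: np.ndarray | None = None,
    n_params: int = 0,
) -> tuple[float, float | None]:
    """Masked chi-square of a prediction against observations with sd.

    Returns ``(chi2, reduced)`` where ``reduced = chi2 / (N - n_params)``;
    ``reduced`` is ``None`` (flagged undefined) when the denominator is not
    positive.  Requires a shared position grid and positive sd on every
    masked point.
    """
    if not np.array_equal(predicted.positions, observed.positions):
        raise ValueError("prediction and observation grids differ")
    if observed.sd is None:
        raise ValueError("observed profile carries no standard deviations")
    if mask is None:
        mask = np.ones(len(observed), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != observed.positions.shape:
        raise ValueError("mask length must match the grid")
    sd = observed.sd[mask]
    if np.any(sd <= 0):
        raise ValueError("sd must be positive on masked points")
    resid = (predicted.values[mask] - observed.values[mask]) / sd
    chi2 = float(np.sum(resid**2))
    dof = int(mask.sum()) - n_params
    reduced = chi2 / dof if dof > 0 else None
    return chi2, reduced


def range_mask(positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask selecting grid points with lo <= x <= hi."""
    positions = np.asarray(positions)
    return (positions >= lo) & (positions <= hi)


@dataclass
class FitProblem:
    """A parameter-estimation problem over positive, log-scaled parameters.

    ``predict(params)`` maps a name->value parameter mapping to predicted
    profiles on the data grid for every fitted species.  ``bounds`` are
    inclusive positive (low, high) pairs per parameter; the GA searches
    their log10 box.
    """

    predict: Callable[[Mapping[str, float]], SpatialField]
    data: SpatialField
    bounds: dict[str, tuple[float, float]]
    masks: Mapping[str, np.ndarray] | None = None
    #: optional vectorized scorer: list of parameter mappings -> objective
    #: array; used by the GA to evaluate a whole population at once
    objective_batch: Callable[[Sequence[Mapping[str, float]]], np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi and math.isfinite(hi)):
                raise ValueError(f"bounds for {name} must be finite and positive")
        if self.masks:
            for s, m in self.masks.items():
                if not np.any(m):
                    raise ValueError(f"mask for {s} selects no points")

    @property
    def parameter_names(self) -> list[str]:
        return list(self.bounds)

    def mask_for(self, species: str) -> np.ndarray | None:
        if self.masks is None:
            return None
        return self.masks.get(species)

    def objective(self, params: Mapping[str, float]) -> float:
        """Sum of masked chi-squares over all fitted species (+inf on
        simulation failure)."""
        try:
            pred = self.predict(params)
        except Exception:
            return float("inf")
        total = 0.0
        for species, obs in self.data.items():
            c2, _ = chi_square(pred[species], obs, self.mask_for(species))
            total += c2
        if not math.isfinite(total):
            return float("inf")
        return total

    def per_species_chi2(
        self, params: Mapping[str, float]
    ) -> dict[str, tuple[float, float | None]]:
        pred = self.predict(params)
        n_p = len(self.bounds)
        return {
            s: chi_square(pred[s], obs, self.mask_for(s), n_params=n_p)
            for s, obs in self.data.items()
        }


@dataclass(frozen=True)
class GAConfig:
    population: int = 200
    generations: int = 500
    tournament: int = 4
    crossover_rate: float = 0.4
    #: probability of differential recombination (step along a random
    #: population difference vector) instead of blend crossover
    differential_rate: float = 0.4
    mutation_rate: float = 0.35
    #: mutation steps are Gaussian in log10 space with a per-offspring
    #: sigma drawn log-uniformly from [mutation_sigma_min, mutation_sigma];
    #: the mix of coarse and fine scales covers exploration and refinement
    mutation_sigma: float = 0.5
    mutation_sigma_min: float = 0.005
    elites: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.population, self.generations, self.tournament) <= 0:
            raise ValueError("population, generations, tournament must be positive")
        for r in (self.crossover_rate, self.mutation_rate, self.differential_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.crossover_rate + self.differential_rate > 1.0:
            raise ValueError("crossover_rate + differential_rate must be <= 1")
        if not 0 < self.mutation_sigma_min <= self.mutation_sigma:
            raise ValueError("need 0 < mutation_sigma_min <= mutation_sigma")
        if self.elites < 0:
            raise ValueError("elites must be non-negative")


@dataclass
class FitResult:
    best_parameters: dict[str, float]
    objective: float
    per_species: dict[str, tuple[float, float | None]]
    trace: list[float] = field(default_factory=list)   # best-so-far per generation
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "best_parameters": self.best_parameters,
            "objective": self.objective,
            "per_species_chi2": {
                s: {"chi2": c, "reduced_chi2": r}
                for s, (c, r) in self.per_species.items()
            },
            "trace": self.trace,
            "n_evaluations": self.n_evaluations,
        }


def ga_minimize(
    problem: FitProblem,
    config: GAConfig = GAConfig(),
    x0: Mapping[str, float] | None = None,
    target_objective: float | None = None,
) -> FitResult:
    """Generational GA over the log10 parameter box.

    Deterministic under ``config.seed``.  ``x0`` optionally injects one
    individual into the initial population (e.g. a previous fit).
    ``target_objective`` stops early once the best objective falls at or
    below it; by default the full generation budget is used.  The returned
    trace is the best-so-far objective per generation and is non-increasing
    by construction (elitism).
    """
    rng = np.random.default_rng(config.seed)
    names = problem.parameter_names
    d = len(names)
    lo = np.log10([problem.bounds[n][0] for n in names])
    hi = np.log10([problem.bounds[n][1] for n in names])

    def decode(z: np.ndarray) -> dict[str, float]:
        return {n: float(10.0 ** z[i]) for i, n in enumerate(names)}

    n_eval = 0

    def score_all(zs: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += len(zs)
        if problem.objective_batch is not None:
            out = np.asarray(problem.objective_batch([decode(z) for z in zs]),
                             dtype=float)
            return np.where(np.isfinite(out), out, np.inf)
        return np.array([problem.objective(decode(z)) for z in zs])

    pop = rng.uniform(lo, hi, size=(config.population, d))
    if x0 is not None:
        pop[0] = np.clip(np.log10([x0[n] for n in names]), lo, hi)
    fitness = score_all(pop)
    if not np.any(np.isfinite(fitness)):
        raise RuntimeError(
            "every individual of the initial population failed to simulate"
        )

    order = np.argsort(fitness)
    best_z, best_f = pop[order[0]].copy(), float(fitness[order[0]])
    trace = [best_f]

    for _ in range(config.generations):
        if target_objective is not None and best_f <= target_objective:
            break
        new = [pop[i].copy() for i in order[: config.elites]]
        while len(new) < config.population:
            a = _tournament(rng, fitness, config.tournament)
            b = _tournament(rng, fitness, config.tournament)
            child = pop[a].copy()
            u = rng.random()
            if u < config.differential_rate:
                # differential recombination: step along a population
                # difference vector — follows the valley directions of
                # sloppy objectives far better than isotropic mutation
                r1, r2 = rng.integers(0, config.population, size=2)
                F = rng.uniform(0.4, 0.9)
                child = pop[a] + F * (pop[r1] - pop[r2])
            elif u < config.differential_rate + config.crossover_rate:
                # blend crossover: per-gene convex mix with slight extrapolation
                w = rng.uniform(-0.1, 1.1, size=d)
                child = w * pop[a] + (1.0 - w) * pop[b]
            mut = rng.random(d) < config.mutation_rate
            sigma = 10.0 ** rng.uniform(
                np.log10(config.mutation_sigma_min),
                np.log10(config.mutation_sigma),
            )
            child[mut] += rng.normal(0.0, sigma, size=int(mut.sum()))
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fitness = score_all(pop)
        order = np.argsort(fitness)
        if fitness[order[0]] < best_f:
            best_f = float(fitness[order[0]])
            best_z = pop[order[0]].copy()
        trace.append(best_f)

    best = decode(best_z)
    per_species = problem.per_species_chi2(best)
    return FitResult(best, best_f, per_species, trace, n_eval)


def _tournament(rng: np.random.Generator, fitness: np.ndarray, k: int) -> int:
    idx = rng.integers(0, len(fitness), size=k)
    return int(idx[np.argmin(fitness[idx])])
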