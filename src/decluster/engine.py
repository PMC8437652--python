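"""Generic differential-evolution machinery.

Population state, the three classical mutation strategies, binomial
crossover, greedy selection, and the population-diversity indicator
lambda(g) = sigma(g) / ||mu(g)|| that drives the double-mutation switch.

Two layers coexist:

* per-individual operations (:func:`mutate_rand_1` etc.) matching the
  textbook formulas one vector at a time, and
* ``batch_*`` counterparts that build a whole generation of mutants/trials
  at once; the clustering drivers use these for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Individual",
    "Population",
    "DEConfig",
    "DiversityState",
    "init_population",
    "mutate_rand_1",
    "mutate_best_1",
    "mutate_current_to_best_1",
    "binomial_crossover",
    "select",
    "diversity_lambda",
    "batch_distinct_indices",
    "batch_mutants",
    "batch_crossover",
]

_MIN_POPULATION = 4  # rand/1 mutation needs three distinct partners


@dataclass
class Individual:
    """One candidate solution: a flat real gene vector plus optional fitness."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.float64).ravel()
        if self.genes.size < 1:
            raise ValueError("an individual needs at least one gene")
        if not np.all(np.isfinite(self.genes)):
            raise ValueError("genes must be finite")


@dataclass
class DEConfig:
    """Control parameters for a DE run.

    ``strategy`` selects the mutation rule; ``double_mutation`` switches
    between rand/1 (population collapsed, lambda below threshold) and best/1
    (population still diverse).  ``sigma_mode`` chooses between the mean
    individual-to-centroid distance (default) and its root-mean-square
    variant for sensitivity checks.  ``init`` selects how the clustering
    driver seeds individuals: ``data_rows`` (k distinct random objects per
    individual, the random-center convention) or ``uniform`` (every gene
    uniform within its attribute bounds).
    """

    NP: int
    F: float = 0.6
    CR: float = 0.5
    lambda_threshold: float = 0.005
    max_generations: int = 1500
    stagnation_limit: int = 400
    seed: int | None = None
    strategy: str = "double_mutation"
    sigma_mode: str = "mean"
    init: str = "data_rows"
    lloyd_refine: bool = False

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be > 0")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must lie in [0, 1]")
        if self.NP < _MIN_POPULATION:
            raise ValueError(f"NP must be >= {_MIN_POPULATION}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.stagnation_limit < 1:
            raise ValueError("stagnation_limit must be >= 1")
        if self.lambda_threshold < 0:
            raise ValueError("lambda_threshold must be >= 0")
        if self.strategy not in {"rand_1", "best_1", "current_to_best_1", "double_mutation"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.sigma_mode not in {"mean", "rms"}:
            raise ValueError("sigma_mode must be 'mean' or 'rms'")
        if self.init not in {"data_rows", "uniform"}:
            raise ValueError("init must be 'data_rows' or 'uniform'")


class Population:
    """NP individuals stored as a dense (NP, D) gene matrix plus fitnesses.

    ``fitness`` entries start as NaN (unevaluated); ``best_index`` is the
    argmin of the evaluated fitnesses.  Any size >= 1 is a valid population
    (the diversity indicator is defined for all of them); the mutation
    operators themselves refuse to run below NP = 4.
    """

    def __init__(self, genes: np.ndarray, bounds: np.ndarray, generation: int = 0):
        genes = np.asarray(genes, dtype=np.float64)
        if genes.ndim != 2:
            raise ValueError("genes must be (NP, D)")
        if genes.shape[0] < 1:
            raise ValueError("population must hold at least one individual")
        bounds = np.asarray(bounds, dtype=np.float64)
        if bounds.shape != (genes.shape[1], 2):
            raise ValueError("bounds must be (D, 2)")
        self.genes = genes
        self.bounds = bounds
        self.generation = int(generation)
        self.fitness = np.full(genes.shape[0], np.nan)

    @property
    def NP(self) -> int:
        return self.genes.shape[0]

    @property
    def D(self) -> int:
        return self.genes.shape[1]

    @property
    def best_index(self) -> int:
        if np.isnan(self.fitness).any():
            raise RuntimeError("best_index requires all fitnesses to be evaluated")
        return int(np.argmin(self.fitness))

    def member(self, i: int) -> Individual:
        f = self.fitness[i]
        return Individual(self.genes[i].copy(), None if math.isnan(f) else float(f))


@dataclass(frozen=True)
class DiversityState:
    """Snapshot of population spread: centroid mu, mean distance sigma, ratio lam."""

    mu: np.ndarray
    sigma: float
    lam: float


def init_population(bounds: np.ndarray, config: DEConfig, rng: np.random.Generator) -> Population:
    """Draw each gene of each individual uniformly from its bound interval."""
    bounds = np.asarray(bounds, dtype=np.float64)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be (D, 2) pairs of (min, max)")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("inverted bounds: min > max")
    genes = rng.uniform(bounds[:, 0], bounds[:, 1], size=(config.NP, bounds.shape[0]))
    return Population(genes, bounds, generation=0)


def _draw_distinct(rng: np.random.Generator, NP: int, exclude: int, count: int) -> list[int]:
    pool = [j for j in range(NP) if j != exclude]
    picks = rng.choice(len(pool), size=count, replace=False)
    return [pool[p] for p in picks]


def mutate_rand_1(pop: Population, i: int, F: float, rng: np.random.Generator) -> np.ndarray:
    """DE/rand/1: v = x_r1 + F (x_r2 - x_r3), r1,r2,r3 distinct and != i."""
    if pop.NP < _MIN_POPULATION:
        raise ValueError("rand/1 mutation needs NP >= 4")
    r1, r2, r3 = _draw_distinct(rng, pop.NP, i, 3)
    return pop.genes[r1] + F * (pop.genes[r2] - pop.genes[r3])


def mutate_best_1(pop: Population, i: int, F: float, rng: np.random.Generator) -> np.ndarray:
    """DE/best/1: v = x_best + F (x_r1 - x_r2), r1 != r2, both != i."""
    if pop.NP < _MIN_POPULATION:
        raise ValueError("best/1 mutation needs NP >= 4")
    best = pop.best_index
    r1, r2 = _draw_distinct(rng, pop.NP, i, 2)
    return pop.genes[best] + F * (pop.genes[r1] - pop.genes[r2])


def mutate_current_to_best_1(pop: Population, i: int, F: float, rng: np.random.Generator) -> np.ndarray:
    """DE/current-to-best/1: v = x_i + F (x_best - x_i) + F (x_r1 - x_r2)."""
    if pop.NP < _MIN_POPULATION:
        raise ValueError("current-to-best/1 mutation needs NP >= 4")
    best = pop.best_index
    r1, r2 = _draw_distinct(rng, pop.NP, i, 2)
    return (
        pop.genes[i]
        + F * (pop.genes[best] - pop.genes[i])
        + F * (pop.genes[r1] - pop.genes[r2])
    )


def binomial_crossover(
    parent: np.ndarray, mutant: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene Bernoulli mix of parent and mutant.

    Gene j comes from the mutant when ``rand <= CR`` or ``j == j_rand``; the
    forced index guarantees at least one mutant gene even at CR = 0.
    """
    parent = np.asarray(parent, dtype=np.float64).ravel()
    mutant = np.asarray(mutant, dtype=np.float64).ravel()
    if parent.shape != mutant.shape:
        raise ValueError("parent and mutant must have the same length")
    D = parent.size
    take = rng.random(D) <= CR
    take[rng.integers(0, D)] = True
    return np.where(take, mutant, parent)


def select(parent: Individual, trial: Individual) -> Individual:
    """Greedy selection: keep the trial only on a strict fitness improvement."""
    if parent.fitness is None or trial.fitness is None:
        raise RuntimeError("select requires both fitnesses to be evaluated")
    return trial if trial.fitness < parent.fitness else parent


def diversity_lambda(pop: Population, sigma_mode: str = "mean") -> DiversityState:
    """Population-diversity indicator.

    mu is the coordinate-wise mean of the individuals, sigma the mean
    Euclidean distance from each individual to mu (or the RMS distance when
    ``sigma_mode='rms'``), and lam = sigma / ||mu||.

    A fully collapsed population yields lam = 0 regardless of where it sits.
    If the population is spread but centred exactly at the origin, lam is
    +inf — a flagged sentinel that the double-mutation switch reads as
    "diverse".
    """
    mu = pop.genes.mean(axis=0)
    dists = np.linalg.norm(pop.genes - mu, axis=1)
    if sigma_mode == "rms":
        sigma = float(np.sqrt((dists**2).mean()))
    elif sigma_mode == "mean":
        sigma = float(dists.mean())
    else:
        raise ValueError("sigma_mode must be 'mean' or 'rms'")
    norm_mu = float(np.linalg.norm(mu))
    if sigma == 0.0:
        lam = 0.0
    elif norm_mu == 0.0:
        lam = math.inf
    else:
        lam = sigma / norm_mu
    return DiversityState(mu=mu, sigma=sigma, lam=lam)


# ---------------------------------------------------------------------------
# Batch (whole-generation) counterparts used by the clustering drivers.
# ---------------------------------------------------------------------------


def batch_distinct_indices(rng: np.random.Generator, NP: int, count: int) -> np.ndarray:
    """Draw ``count`` partner indices per target, mutually distinct and != target.

    Returns an (count, NP) integer array; column i holds the partners of
    target i.  Collisions are resolved by redrawing only the offending
    entries, which keeps the expected number of draws near-minimal.
    """
    if NP < count + 1:
        raise ValueError(f"need NP >= {count + 1} for {count} distinct partners")
    target = np.arange(NP)
    out = np.empty((count, NP), dtype=np.int64)
    for c in range(count):
        r = rng.integers(0, NP, size=NP)
        while True:
            bad = r == target
            for prev in range(c):
                bad |= r == out[prev]
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            r[bad] = rng.integers(0, NP, size=n_bad)
        out[c] = r
    return out


def batch_mutants(
    genes: np.ndarray,
    strategy: str,
    F: float,
    rng: np.random.Generator,
    best_index: int | None = None,
) -> np.ndarray:
    """Build one mutant per population member under the given strategy."""
    NP = genes.shape[0]
    if strategy == "rand_1":
        r = batch_distinct_indices(rng, NP, 3)
        return genes[r[0]] + F * (genes[r[1]] - genes[r[2]])
    if strategy == "best_1":
        if best_index is None:
            raise ValueError("best_1 requires best_index")
        r = batch_distinct_indices(rng, NP, 2)
        return genes[best_index] + F * (genes[r[0]] - genes[r[1]])
    if strategy == "current_to_best_1":
        if best_index is None:
            raise ValueError("current_to_best_1 requires best_index")
        r = batch_distinct_indices(rng, NP, 2)
        return genes + F * (genes[best_index] - genes) + F * (genes[r[0]] - genes[r[1]])
    raise ValueError(f"unknown mutation strategy {strategy!r}")


def batch_crossover(
    genes: np.ndarray, mutants: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover applied row-wise to a whole generation."""
    NP, D = genes.shape
    take = rng.random((NP, D)) <= CR
    take[np.arange(NP), rng.integers(0, D, size=NP)] = True
    return np.where(take, mutants, genes)
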