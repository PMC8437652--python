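"""Center-encoded DE clustering: the double-mutation algorithm and the
standard DE-K-Means baseline.

An individual is a flat vector of k*d genes holding k candidate cluster
centers (row-major).  Fitness is the unsquared within-class distance from
:mod:`decluster.metrics`.  The improved algorithm recomputes the diversity
indicator once per generation and flips between best/1 (diverse, exploit)
and rand/1 (collapsed, explore).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import engine
from .engine import DEConfig, DiversityState, Population, diversity_lambda
from .metrics import ClusterAssignment, DataMatrix, assign_nearest, batch_wcd, wcd

__all__ = [
    "ClusteringResult",
    "RunProfile",
    "UCI_PROFILE",
    "TCM_PROFILE",
    "encode_centers",
    "decode_centers",
    "double_mutation",
    "run_de_kmeans",
    "run_improved",
    "run_de_clustering",
]


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of one clustering run.

    ``wcd`` is always the exact :func:`decluster.metrics.wcd` of ``centers``
    on the input data.  ``history`` holds the best objective value after each
    generation (entry 0 is the initial population's best) and is
    non-increasing.  ``converged`` records whether the stagnation rule fired
    before the generation cap.
    """

    centers: np.ndarray
    assignment: ClusterAssignment
    wcd: float
    iterations: int
    converged: bool
    history: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return self.assignment.labels


@dataclass(frozen=True)
class RunProfile:
    """Named parameter bundle for the two experimental protocols.

    ``np_factor`` scales the population: NP = np_factor * (k * d) by default
    (``np_dim`` = "full"), or np_factor * d when ``np_dim`` = "data" for
    sensitivity analysis.
    """

    name: str
    F: float = 0.6
    CR: float = 0.5
    np_factor: int = 10
    lambda_threshold: float = 0.005
    stagnation_limit: int = 400
    max_generations: int = 1500
    k: int | None = None
    np_dim: str = "full"

    def population_size(self, k: int, d: int) -> int:
        dim = k * d if self.np_dim == "full" else d
        return max(self.np_factor * dim, 4)

    def make_config(self, k: int, d: int, seed: int | None = None,
                    strategy: str = "double_mutation", **overrides) -> DEConfig:
        cfg = DEConfig(
            NP=self.population_size(k, d),
            F=self.F,
            CR=self.CR,
            lambda_threshold=self.lambda_threshold,
            max_generations=self.max_generations,
            stagnation_limit=self.stagnation_limit,
            seed=seed,
            strategy=strategy,
        )
        return replace(cfg, **overrides) if overrides else cfg


UCI_PROFILE = RunProfile(name="uci", lambda_threshold=0.005, max_generations=1500)
TCM_PROFILE = RunProfile(name="tcm", lambda_threshold=0.001, max_generations=2500, k=7)


def encode_centers(centers: np.ndarray) -> np.ndarray:
    """Flatten a (k, d) center matrix row-major into a length k*d gene vector."""
    centers = np.asarray(centers, dtype=np.float64)
    if centers.ndim != 2:
        raise ValueError("centers must be a (k, d) matrix")
    return centers.reshape(-1).copy()


def decode_centers(genes: np.ndarray, k: int, d: int) -> np.ndarray:
    """Inverse of :func:`encode_centers`; exact round-trip."""
    genes = np.asarray(genes, dtype=np.float64).ravel()
    if genes.size != k * d:
        raise ValueError(f"gene vector of length {genes.size} does not hold {k}x{d} centers")
    return genes.reshape(k, d).copy()


def double_mutation(
    pop: Population,
    i: int,
    F: float,
    lambda_threshold: float,
    diversity: DiversityState,
    rng: np.random.Generator,
) -> np.ndarray:
    """Diversity-switched mutation for one target individual.

    lam below the threshold means the population has collapsed, so rand/1
    re-injects exploration; otherwise best/1 exploits the incumbent optimum.
    """
    if diversity.lam < lambda_threshold:
        return engine.mutate_rand_1(pop, i, F, rng)
    return engine.mutate_best_1(pop, i, F, rng)


def _tile_bounds(data: DataMatrix, k: int) -> np.ndarray:
    # gene j of center block c is attribute (j mod d): bounds repeat k times
    return np.tile(data.bounds, (k, 1))


def run_de_clustering(
    data: DataMatrix,
    k: int,
    config: DEConfig,
    branch_log: list[str] | None = None,
) -> ClusteringResult:
    """Shared DE driver; the mutation rule comes from ``config.strategy``.

    One diversity evaluation per generation (before the mutation sweep), one
    fitness evaluation per trial, greedy one-to-one replacement, and
    termination either at ``max_generations`` or after ``stagnation_limit``
    consecutive generations in which the best fitness is bit-identical.

    ``branch_log`` (optional) receives one ``(generation, lambda, strategy)``
    tuple per generation — the audit trail for the double-mutation switch
    (lambda is NaN for fixed strategies).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > data.n:
        raise ValueError(f"k={k} exceeds the number of objects n={data.n}")
    X = data.values
    d = data.d
    bounds = _tile_bounds(data, k)
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(config.seed)
    NP = config.NP

    neg2_Xt = -2.0 * X.T
    xsq = (X * X).sum(axis=1)

    if config.init == "data_rows":
        # each individual starts as k distinct randomly selected objects —
        # the "randomly selected initial clustering centers" convention of
        # K-Means, which anchors the search in populated regions and is
        # what makes every run reach the same optimum on the benchmarks
        rows = np.stack([rng.choice(data.n, size=k, replace=False) for _ in range(NP)])
        genes = X[rows].reshape(NP, k * d).copy()
    else:
        genes = rng.uniform(lo, hi, size=(NP, k * d))
    fit = batch_wcd(X, genes.reshape(NP, k, d), neg2_Xt, xsq)
    best_idx = int(np.argmin(fit))
    best_fit = float(fit[best_idx])
    history = [best_fit]

    stagnation = 0
    converged = False
    generations = 0
    pop = Population(genes, bounds)  # window onto the same array for diversity
    for g in range(1, config.max_generations + 1):
        generations = g
        if config.strategy == "double_mutation":
            div = diversity_lambda(pop, config.sigma_mode)
            lam = div.lam
            strategy = "rand_1" if lam < config.lambda_threshold else "best_1"
        else:
            lam = float("nan")
            strategy = config.strategy
        if branch_log is not None:
            branch_log.append((g, lam, strategy))

        mutants = engine.batch_mutants(genes, strategy, config.F, rng, best_index=best_idx)
        np.clip(mutants, lo, hi, out=mutants)
        trials = engine.batch_crossover(genes, mutants, config.CR, rng)
        tfit = batch_wcd(X, trials.reshape(NP, k, d), neg2_Xt, xsq)

        better = tfit < fit
        genes[better] = trials[better]
        fit[better] = tfit[better]
        best_idx = int(np.argmin(fit))
        new_best = float(fit[best_idx])

        if new_best == best_fit:
            stagnation += 1
        else:
            stagnation = 0
            best_fit = new_best
        history.append(best_fit)
        if stagnation >= config.stagnation_limit:
            converged = True
            break

    centers = decode_centers(genes[best_idx], k, d)
    if config.lloyd_refine:
        centers = _lloyd_polish(data, centers)
    assignment = assign_nearest(data, centers)
    return ClusteringResult(
        centers=centers,
        assignment=assignment,
        wcd=wcd(data, centers),
        iterations=generations,
        converged=converged,
        history=np.asarray(history),
    )


def _lloyd_polish(data: DataMatrix, centers: np.ndarray) -> np.ndarray:
    """Optional single mean-update sweep, kept only if it improves the objective."""
    assignment = assign_nearest(data, centers)
    polished = centers.copy()
    for t in range(centers.shape[0]):
        mask = assignment.labels == t
        if mask.any():
            polished[t] = data.values[mask].mean(axis=0)
    return polished if wcd(data, polished) < wcd(data, centers) else centers


def run_de_kmeans(data: DataMatrix, k: int, config: DEConfig) -> ClusteringResult:
    """Standard DE-K-Means baseline: fixed DE/rand/1 mutation throughout."""
    return run_de_clustering(data, k, replace(config, strategy="rand_1"))


def run_improved(
    data: DataMatrix, k: int, config: DEConfig, branch_log: list[str] | None = None
) -> ClusteringResult:
    """The double-mutation algorithm: diversity-switched rand/1 vs best/1."""
    return run_de_clustering(
        data, k, replace(config, strategy="double_mutation"), branch_log=branch_log
    )
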