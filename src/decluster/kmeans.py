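"""Lloyd's K-Means and K-Means++ seeding — the non-evolutionary baselines.

Lloyd iterates on the classical squared-error objective, but the reported
``wcd`` is always the unsquared within-class distance evaluated on the final
solution, so results are directly comparable with the DE optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import ClusteringResult
from .metrics import DataMatrix, assign_nearest, wcd

__all__ = ["KMeansConfig", "kmeans_pp_seed", "run_kmeans"]


@dataclass
class KMeansConfig:
    k: int
    max_iterations: int = 300
    seed: int | None = None
    init: str = "random_points"  # or "kmeans_pp"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.init not in {"random_points", "kmeans_pp"}:
            raise ValueError(f"unknown init {self.init!r}")


def kmeans_pp_seed(data: DataMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    """D^2 seeding: each new center is a data row drawn with probability
    proportional to its squared distance to the nearest already-chosen center.

    Returns k distinct data rows.  Already-chosen rows have zero weight, so
    k = n yields a permutation of the data.
    """
    if k > data.n:
        raise ValueError(f"k={k} exceeds n={data.n}")
    X = data.values
    chosen = np.empty(k, dtype=np.intp)
    chosen[0] = rng.integers(0, data.n)
    d2 = ((X - X[chosen[0]]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total > 0:
            probs = d2 / total
            chosen[c] = rng.choice(data.n, p=probs)
        else:
            # duplicate-heavy data: fall back to a uniform unchosen row
            remaining = np.setdiff1d(np.arange(data.n), chosen[:c])
            chosen[c] = rng.choice(remaining)
        d2 = np.minimum(d2, ((X - X[chosen[c]]) ** 2).sum(axis=1))
    return X[chosen].copy()


def run_kmeans(data: DataMatrix, config: KMeansConfig) -> ClusteringResult:
    """Lloyd iteration until the assignment stops changing.

    The iteration count includes the final confirming pass (a run that starts
    at the fixed point still reports 2 iterations: one to settle, one to
    confirm).  An emptied cluster is re-seeded at the point farthest from its
    current center.
    """
    if config.k > data.n:
        raise ValueError(f"k={config.k} exceeds n={data.n}")
    X = data.values
    rng = np.random.default_rng(config.seed)
    if config.init == "kmeans_pp":
        centers = kmeans_pp_seed(data, config.k, rng)
    else:
        centers = X[rng.choice(data.n, size=config.k, replace=False)].copy()

    labels = None
    history = []
    converged = False
    iterations = 0
    for it in range(1, config.max_iterations + 1):
        iterations = it
        new_labels = assign_nearest(data, centers).labels
        if labels is not None and np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for t in range(config.k):
            mask = labels == t
            if mask.any():
                centers[t] = X[mask].mean(axis=0)
            else:
                far = int(np.argmax(cdist(X, centers[t][None, :]).ravel()))
                centers[t] = X[far]
        history.append(wcd(data, centers))

    assignment = assign_nearest(data, centers)
    return ClusteringResult(
        centers=centers,
        assignment=assignment,
        wcd=wcd(data, centers),
        iterations=iterations,
        converged=converged,
        history=np.asarray(history) if history else np.asarray([wcd(data, centers)]),
    )
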