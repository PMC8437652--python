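"""Independent brute-force oracles shared by the clustering and acceptance tests."""

import itertools
import math

import numpy as np


def geometric_median(P, iters=500, tol=1e-13):
    """Weiszfeld iteration with singleton handling; independent of the DE path."""
    P = np.asarray(P, dtype=float)
    if len(P) == 1:
        return P[0]
    y = P.mean(axis=0)
    for _ in range(iters):
        d = np.linalg.norm(P - y, axis=1)
        if np.any(d < 1e-14):
            y = y + 1e-10  # nudge off a data point; adequate at toy scale
            d = np.linalg.norm(P - y, axis=1)
        w = 1.0 / d
        y_new = (P * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def bruteforce_wcd_minimum(X, k):
    """Exhaustive minimum of the unsquared within-class distance over all
    k-labelings, each cluster centered at its geometric median."""
    best = math.inf
    for lab in itertools.product(range(k), repeat=len(X)):
        lab = np.asarray(lab)
        total = 0.0
        for t in range(k):
            rows = X[lab == t]
            if len(rows) == 0:
                continue
            c = geometric_median(rows)
            total += np.linalg.norm(rows - c, axis=1).sum()
        best = min(best, total)
    return best
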