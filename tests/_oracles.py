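"""Independent brute-force oracles used across the test suite."""

import numpy as np


def brute_force_min_distance(xa: np.ndarray, xb: np.ndarray) -> float:
    """O(n*m) double-loop minimum pairwise distance."""
    best = np.inf
    for p in np.atleast_2d(xa):
        for q in np.atleast_2d(xb):
            d = float(np.sqrt(((p - q) ** 2).sum()))
            if d < best:
                best = d
    return best


def brute_force_min_self_distance(xa: np.ndarray) -> float:
    """Smallest distance over distinct pairs within one point set."""
    xa = np.atleast_2d(xa)
    best = np.inf
    for i in range(len(xa)):
        for j in range(i + 1, len(xa)):
            d = float(np.sqrt(((xa[i] - xa[j]) ** 2).sum()))
            if d < best:
                best = d
    return best
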