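"""Independent naive recomputation of the outranking method for tests.

Deliberately written as plain double loops over ordered pairs, with no code
shared with the package pipeline, so the two routes can be compared. Only the
paper-linear preference function is supported (the case the oracle checks).
"""

from __future__ import annotations

import numpy as np


def naive_normalize(scores: np.ndarray, directions: list[str]) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    m, k = scores.shape
    t = np.zeros((m, k))
    for j in range(k):
        lo = min(scores[:, j])
        hi = max(scores[:, j])
        if hi == lo:
            continue
        for i in range(m):
            if directions[j] == "beneficial":
                t[i, j] = (scores[i, j] - lo) / (hi - lo)
            else:
                t[i, j] = (hi - scores[i, j]) / (hi - lo)
    return t


def naive_flows(
    scores: np.ndarray, weights, directions: list[str] | None = None
):
    """phi+, phi-, phi by brute force (full precision, paper-linear)."""
    scores = np.asarray(scores, dtype=float)
    m, k = scores.shape
    if directions is None:
        directions = ["beneficial"] * k
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    t = naive_normalize(scores, directions)

    phi_plus = np.zeros(m)
    phi_minus = np.zeros(m)
    for z in range(m):
        for y in range(m):
            if z == y:
                continue
            pi_zy = 0.0
            for j in range(k):
                d = t[z, j] - t[y, j]
                if d > 0:
                    pi_zy += w[j] * min(d, 1.0)
            phi_plus[z] += pi_zy
            phi_minus[y] += pi_zy
    phi_plus /= m - 1
    phi_minus /= m - 1
    return phi_plus, phi_minus, phi_plus - phi_minus


def naive_ranks(phi: np.ndarray) -> list[int]:
    return [1 + sum(1 for other in phi if other > v) for v in phi]
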