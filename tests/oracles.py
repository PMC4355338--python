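"""Independent oracles used by the tests.

These deliberately avoid the package's dynamic-programming and SVD code
paths: alignment scores come from exhaustive enumeration of every global
alignment, and superposition optima from a random-restart direct search
over rotations.
"""

from __future__ import annotations

import numpy as np

_D, _U, _L = 0, 1, 2  # diagonal, gap-in-B (consumes A), gap-in-A


def brute_force_align_score(a: str, b: str, sub, index, gap_open, gap_extend):
    """Best affine-gap global alignment score by enumerating all paths.

    A gap run of length k costs open + (k-1) * extend; runs in the two
    sequences are penalized independently. Exponential — lengths <= 7.
    """
    ea = [index[c] for c in a]
    eb = [index[c] for c in b]
    n, m = len(ea), len(eb)
    best = [-np.inf]

    def rec(i, j, score, last):
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            rec(i + 1, j + 1, score + sub[ea[i], eb[j]], _D)
        if i < n:
            cost = gap_extend if last == _U else gap_open
            rec(i + 1, j, score - cost, _U)
        if j < m:
            cost = gap_extend if last == _L else gap_open
            rec(i, j + 1, score - cost, _L)

    rec(0, 0, 0.0, _D)
    return best[0]


def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def search_min_rmsd(moving: np.ndarray, fixed: np.ndarray, n_starts: int = 24,
                    seed: int = 0) -> float:
    """Minimal RMSD via Nelder-Mead over rotation vectors, random restarts.

    Translation is handled in closed form (centroid match), which is exact
    for any rotation; only the rotation is searched.
    """
    from scipy.optimize import minimize

    a = moving - moving.mean(axis=0)
    b = fixed - fixed.mean(axis=0)
    n = a.shape[0]

    def rmsd_of(v):
        r = _rotvec_to_matrix(np.asarray(v))
        return float(np.sqrt(((a @ r.T - b) ** 2).sum() / n))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, size=3)
        res = minimize(rmsd_of, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, float(res.fun))
    return best
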