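"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (loops, exhaustive enumeration)
and shares no code with the package internals it verifies.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_local_cc(a: np.ndarray, b: np.ndarray, radius: int) -> np.ndarray:
    """Windowed squared NCC by direct loops with partial windows."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    out = np.zeros(a.shape)
    nx, ny, nz = a.shape
    r = radius
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                sl = (
                    slice(max(i - r, 0), min(i + r + 1, nx)),
                    slice(max(j - r, 0), min(j + r + 1, ny)),
                    slice(max(k - r, 0), min(k + r + 1, nz)),
                )
                wa = a[sl].ravel() - a[sl].mean()
                wb = b[sl].ravel() - b[sl].mean()
                denom = np.dot(wa, wa) * np.dot(wb, wb)
                if denom > 0:
                    out[i, j, k] = np.dot(wa, wb) ** 2 / denom
    return out


def ecdf_ks_statistic(x, y) -> float:
    """KS D by sweeping every observed value against both ECDFs."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    d = 0.0
    for v in np.concatenate([x, y]):
        fx = np.mean(x <= v)
        fy = np.mean(y <= v)
        d = max(d, abs(fx - fy))
    return d


def permutation_ks_pvalue(x, y, n_perm: int, seed: int = 0) -> float:
    """Monte-Carlo permutation p-value for the two-sample KS statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d_obs = ecdf_ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if ecdf_ks_statistic(perm[: x.size], perm[x.size :]) >= d_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def exhaustive_marker_matching(ref: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Best assignment of candidate centroids to reference markers by
    total distance, over all permutations."""
    ref = np.asarray(ref, float)
    cand = np.asarray(cand, float)
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(len(cand))):
        cost = sum(
            np.linalg.norm(ref[i] - cand[p]) for i, p in enumerate(perm)
        )
        if cost < best_cost:
            best_cost, best = cost, perm
    return cand[list(best)]
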