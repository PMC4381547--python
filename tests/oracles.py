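"""Independent reference implementations used only for cross-checking.

These deliberately use different algorithms from the package: recursive
kinship coefficients instead of the tabular relationship matrix, a direct
dense marker-equation solve instead of the individual-level mixed-model
equations, and brute-force enumeration for small clustering problems.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from wgblup.data import UNKNOWN_PARENT, Pedigree


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """2x recursive kinship coefficients (Malecot recursion)."""
    ids = list(ped.ids)
    pos = {i: k for k, i in enumerate(ids)}
    sire = {ids[k]: ped.sires[k] for k in range(len(ids))}
    dam = {ids[k]: ped.dams[k] for k in range(len(ids))}

    @lru_cache(maxsize=None)
    def phi(a: str, b: str) -> float:
        if a == UNKNOWN_PARENT or b == UNKNOWN_PARENT:
            return 0.0
        # recurse on the individual appearing later in pedigree order
        if pos[a] < pos[b]:
            a, b = b, a
        if a == b:
            return 0.5 * (1.0 + phi(sire[a], dam[a]))
        return 0.5 * (phi(sire[a], b) + phi(dam[a], b))

    n = len(ids)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            K[i, j] = K[j, i] = 2.0 * phi(ids[i], ids[j])
    return K


def snp_blup_predictions(y: np.ndarray, Z: np.ndarray, weights: np.ndarray,
                         lam: float, scale: float) -> np.ndarray:
    """Ridge SNP-BLUP with per-marker penalties matching a weighted GRM.

    Solves min ||y - 1 mu - Z_s beta||^2 + lam * scale * beta' D^-1 beta
    over the markers with positive weight (D = diag(w/sum w)); returns the
    individual predictions Z_s beta (the GEBV part, without mu).
    """
    pos = weights > 0
    Zs = Z[:, pos]
    d = weights[pos] / weights.sum()
    n, ms = Zs.shape
    C = np.zeros((ms + 1, ms + 1))
    C[0, 0] = n
    C[0, 1:] = Zs.sum(axis=0)
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = Zs.T @ Zs + lam * scale * np.diag(1.0 / d)
    rhs = np.concatenate(([y.sum()], Zs.T @ y))
    sol = np.linalg.solve(C, rhs)
    return Zs @ sol[1:]


def gls_marker_fit(y: np.ndarray, x: np.ndarray, V: np.ndarray):
    """Direct generalized least squares of y on [1, x]; returns the marker
    coefficient and its Wald F statistic under known V."""
    X = np.column_stack([np.ones_like(y), x])
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    cov = np.linalg.inv(XtVi @ X)
    b = cov @ (XtVi @ y)
    f = b[1] ** 2 / cov[1, 1]
    return b[1], f


def best_two_medoids(D: np.ndarray):
    """Exhaustive 2-medoid solution: (cost, medoid pair, labels)."""
    n = D.shape[0]
    best = None
    for pair in itertools.combinations(range(n), 2):
        sub = D[:, pair]
        lab = np.argmin(sub, axis=1)
        cost = sub[np.arange(n), lab].sum()
        if best is None or cost < best[0] - 1e-12:
            best = (cost, pair, lab)
    return best
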