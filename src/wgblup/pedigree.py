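"""Numerator relationship matrix, relationship distance and k-medoids folds.

The additive (numerator) relationship matrix A is built with the tabular
method.  Cross-validation folds are obtained by clustering individuals on
the relationship-derived distance d_ij = 1 - a_ij / sqrt(a_ii * a_jj) with
the PAM (partitioning-around-medoids) algorithm, so that folds maximize
within-group and minimize between-group genetic relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Pedigree, ValidationError

__all__ = ["RelationshipMatrix", "DistanceMatrix", "FoldAssignment",
           "build_A", "rel_distance", "kmedoids"]


@dataclass
class RelationshipMatrix:
    ids: list
    values: np.ndarray
    kind: str  # "A", "G_base", or "G_<scheme>"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("relationship matrix not symmetric")

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=np.intp)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  self.kind)


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("distance matrix diagonal not zero")


@dataclass
class FoldAssignment:
    ids: list
    labels: np.ndarray        # 1..k per individual
    medoid_ids: list
    cost: float = field(default=np.nan)

    @property
    def k(self) -> int:
        return len(self.medoid_ids)

    def fold_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix.

    Processing individuals in pedigree (topological) order:
    a_ii = 1 + 0.5 a(sire,dam) and a_ij = 0.5 (a(j,sire_i) + a(j,dam_i)),
    with unknown parents contributing zero.
    """
    n = len(ped)
    sire_ix, dam_ix = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(list(ped.ids), A, "A")


def rel_distance(r: RelationshipMatrix, clip: bool = True) -> DistanceMatrix:
    """d_ij = 1 - a_ij / sqrt(a_ii a_jj), with zero diagonal.

    For genomic matrices an off-diagonal can exceed the geometric mean of
    the diagonals; with ``clip`` the resulting negative distance is clipped
    to 0 so the output stays a dissimilarity.
    """
    a = r.values
    diag = np.diag(a)
    if np.any(diag <= 0):
        raise ValidationError("relationship diagonal must be positive")
    denom = np.sqrt(np.outer(diag, diag))
    d = 1.0 - a / denom
    if clip:
        np.clip(d, 0.0, None, out=d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(r.ids), d)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding each candidate: total reduction in nearest distance
        red = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        red[medoids] = -np.inf
        h = int(np.argmax(red))
        medoids.append(h)
        d_near = np.minimum(d_near, D[:, h])
    return medoids


def kmedoids(d: DistanceMatrix, k: int = 4, seed: int = 0,
             max_iter: int = 100) -> FoldAssignment:
    """PAM clustering: greedy build phase followed by best-improvement
    swaps.  The build phase is deterministic; ``seed`` only breaks exact
    ties in the swap phase.  Assignment ties go to the lowest medoid index.
    """
    D = d.values
    n = D.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds {n} individuals")
    rng = np.random.default_rng(seed)
    medoids = _pam_build(D, k)

    def assign(meds):
        sub = D[:, meds]
        nearest = np.argmin(sub, axis=1)  # ties -> lowest index
        return nearest, sub

    for _ in range(max_iter):
        meds = np.array(sorted(medoids))
        nearest, sub = assign(meds)
        d1 = sub[np.arange(n), nearest]
        cost = d1.sum()
        best = (0.0, None)
        for r_pos in range(k):
            others = np.delete(np.arange(k), r_pos)
            if len(others):
                base = np.min(sub[:, others], axis=1)  # nearest among kept
            else:
                base = np.full(n, np.inf)
            cand = np.setdiff1d(np.arange(n), meds, assume_unique=False)
            if len(cand) == 0:
                break
            newcosts = np.minimum(base[:, None], D[:, cand]).sum(axis=0)
            j = int(np.argmin(newcosts))
            delta = newcosts[j] - cost
            if delta < best[0] - 1e-12:
                best = (delta, (r_pos, int(cand[j])))
            elif best[1] is not None and abs(delta - best[0]) <= 1e-12:
                if rng.random() < 0.5:  # exact tie between improving swaps
                    best = (delta, (r_pos, int(cand[j])))
        if best[1] is None:
            break
        r_pos, h = best[1]
        medoids = list(meds)
        medoids[r_pos] = h

    meds = np.array(sorted(medoids))
    nearest, sub = assign(meds)
    cost = float(sub[np.arange(n), nearest].sum())
    return FoldAssignment(list(d.ids), nearest + 1,
                          [d.ids[i] for i in meds], cost)
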