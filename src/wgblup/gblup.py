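"""Mixed-model equations for (weighted) GBLUP and variance-ratio selection.

Given phenotypes y on a subset of the individuals covered by a
relationship matrix K (pedigree A or any genomic G), the block system

    [ 1'R"1     1'R"Z          ] [mu]   [1'R"y]
    [ Z'R"1     Z'R"Z + K^-1 l ] [u ] = [Z'R"y]

is solved for the population mean and the additive values of all
individuals, where Z is the incidence of phenotyped records on
individuals, l = (1-h2)/h2 is the residual-to-genetic variance ratio, and
R" is the inverse residual weight matrix (identity under the default
"product" phenotype weighting, diag(w) under "residual" weighting).
Masked individuals keep zero incidence rows and are predicted purely
through the K^-1 coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data import TraitTable, ValidationError
from .pedigree import RelationshipMatrix

__all__ = ["MMESolution", "weight_phenotypes", "solve_mme", "select_lambda",
           "lambda_from_h2", "DEFAULT_H2_GRID"]

DEFAULT_H2_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


def lambda_from_h2(h2: float) -> float:
    if not (0 < h2 < 1):
        raise ValueError("h2 outside (0,1)")
    return (1.0 - h2) / h2


@dataclass
class MMESolution:
    mu_hat: float
    u_hat: np.ndarray   # one entry per individual in the relationship matrix
    y_hat: np.ndarray   # mu_hat + u_hat
    ids: list


def weight_phenotypes(t: TraitTable, mode: str = "product") -> np.ndarray:
    """Observed record vector for the MME.

    ``product`` (default): y_i = depta_i * w_i (the weighted dePTA).
    ``residual``: y_i = depta_i, with the weight instead entering the
    residual precision of the MME.
    """
    if t.depta is None:
        raise ValidationError("trait table must be de-regressed first")
    if mode == "product":
        return t.depta * t.record_weight
    if mode == "residual":
        return t.depta.copy()
    raise ValueError(f"unknown phenotype weighting mode {mode!r}")


def solve_mme(y: np.ndarray, obs_idx: np.ndarray, K: RelationshipMatrix,
              lam: float, residual_weights: np.ndarray | None = None,
              check_tol: float = 1e-8) -> MMESolution:
    """Solve the mixed-model equations on relationship matrix ``K``.

    ``y`` holds the records of the phenotyped individuals whose positions
    in ``K.ids`` are ``obs_idx``; all other individuals are masked and
    receive predictions through the relationship coupling only.  The dense
    symmetric system is solved by factorization of the absorbed
    (variance-form) equations -- mathematically identical to direct
    inversion of the block system -- and the solution is verified against
    the normal equations at relative tolerance ``check_tol``.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    G = K.values
    obs_idx = np.asarray(obs_idx, dtype=np.intp)
    y = np.asarray(y, dtype=np.float64)
    w = (np.ones(len(y)) if residual_weights is None
         else np.asarray(residual_weights, dtype=np.float64))
    if len(np.unique(obs_idx)) != len(obs_idx):
        raise ValidationError("duplicate records for an individual")

    # Absorb u out of the block system: with V = Z G Z' + lam R the
    # solutions are mu = (1'V"y)/(1'V"1) and u = G Z' V"(y - 1 mu).  This
    # is algebraically identical to solving the G^-1 block equations but
    # stays defined when G is only positive semidefinite (a centered-
    # genotype G always has the ones vector in its null space).
    Gobs = G[np.ix_(obs_idx, obs_idx)]
    V = Gobs + lam * np.diag(1.0 / w)
    try:
        cf = linalg.cho_factor(V, lower=True)
    except (linalg.LinAlgError, ValueError) as exc:
        raise ValidationError(
            "singular mixed-model equations; increase ridge_eps on the "
            "relationship matrix") from exc
    vi_one = linalg.cho_solve(cf, np.ones(len(y)))
    vi_y = linalg.cho_solve(cf, y)
    denom = float(vi_one.sum())
    if denom <= 0:
        raise ValidationError(
            "degenerate mixed-model equations; increase ridge_eps on the "
            "relationship matrix")
    mu = float(vi_y.sum() / denom)
    alpha = vi_y - mu * vi_one
    u = G[:, obs_idx] @ alpha

    resid = np.linalg.norm(V @ alpha - (y - mu))
    scale = max(np.linalg.norm(y), 1e-300)
    if resid / scale > check_tol or abs(alpha.sum()) / scale > check_tol:
        raise ValidationError(
            f"MME solution inaccurate (relative residual {resid / scale:.2e})")
    return MMESolution(mu, u, mu + u, list(K.ids))


def select_lambda(y: np.ndarray, obs_idx: np.ndarray, mask_idx: np.ndarray,
                  y_mask: np.ndarray, K: RelationshipMatrix,
                  h2_grid=DEFAULT_H2_GRID, criterion: str = "abs",
                  residual_weights: np.ndarray | None = None):
    """Pick the variance ratio on a heritability grid.

    For each h2 in the grid, lambda = (1-h2)/h2 and the MME are solved
    with the masked individuals excluded from the records; the criterion
    d = sum |y_i - yhat_i| over the masked records is minimized
    (``criterion="signed"`` uses the literal signed sum instead).
    Returns (best solution, criterion table).
    """
    if len(h2_grid) == 0:
        raise ValueError("empty heritability grid")
    rows = []
    best = None
    for h2 in h2_grid:
        lam = lambda_from_h2(h2)
        sol = solve_mme(y, obs_idx, K, lam, residual_weights)
        diff = y_mask - sol.y_hat[mask_idx]
        d = float(np.abs(diff).sum() if criterion == "abs" else diff.sum())
        rows.append({"h2": float(h2), "lambda": lam, "d": d})
        if best is None or d < best[0]:
            best = (d, sol, float(h2))
    table = pd.DataFrame(rows)
    return best[1], best[2], table
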