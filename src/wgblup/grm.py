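"""Centered genotypes and base/weighted genomic relationship matrices.

A genomic relationship matrix is a weighted sum of single-locus rank-1
matrices G_i = z_i z_i' built from allele-frequency-centered dosages.  The
weight of marker i is its expected variance 2 p_i (1 - p_i) for the base
matrix, optionally multiplied by a trait-specific factor: a selection
indicator from a single-marker scan, or the squared allele-substitution
effect from a whole-genome regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, ValidationError
from .markers import MarkerEffects
from .pedigree import RelationshipMatrix

__all__ = ["CenteredGenotypes", "MarkerWeights", "center", "marker_weights",
           "build_wgrm"]

SCHEMES = ("BASE", "SM", "RR", "BL")


@dataclass
class CenteredGenotypes:
    """Dosages centered by twice the counted-allele frequency."""

    ids: list
    Z: np.ndarray
    p: np.ndarray


@dataclass
class MarkerWeights:
    w: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if not np.all(np.isfinite(self.w)) or np.any(self.w < 0):
            raise ValidationError("marker weights must be finite and >= 0")
        if not np.any(self.w > 0):
            raise ValidationError(
                f"empty weight vector for scheme {self.scheme}")


def center(g: GenotypeMatrix) -> CenteredGenotypes:
    """z_ij = dosage_ij - 2 p_j with p computed on this cohort.

    Equivalent to the subtract-1-then-subtract-t chain (t_i = 2(p_i - 0.5)).
    Monomorphic markers are allowed (their column becomes all zero) but
    flagged with a warning.
    """
    if np.isnan(g.calls).any():
        raise ValidationError("genotypes must be complete before centering")
    p = g.allele_freq()
    if np.any((p == 0.0) | (p == 1.0)):
        warnings.warn("monomorphic markers present; their centered column "
                      "is constant", stacklevel=2)
    return CenteredGenotypes(list(g.individual_ids), g.calls - 2.0 * p, p)


def marker_weights(scheme: str, p: np.ndarray,
                   effects: MarkerEffects | None = None,
                   alpha: float = 0.05) -> MarkerWeights:
    """Per-marker weights for the requested scheme.

    BASE: w_i = 2 p_i (1-p_i).  SM: multiplied by the selection indicator
    S_i (p-value < alpha, strict).  RR/BL: multiplied by the squared
    estimated allele-substitution effect u_i^2.
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    base = 2.0 * p * (1.0 - p)
    if scheme == "BASE":
        return MarkerWeights(base, scheme)
    if effects is None:
        raise ValueError(f"scheme {scheme} requires marker effects")
    if scheme == "SM":
        if effects.p_value is None:
            raise ValueError("SM weights need p-values from sm_scan")
        s = (effects.p_value < alpha).astype(np.float64)
        return MarkerWeights(base * s, scheme)
    return MarkerWeights(base * effects.effect ** 2, scheme)


def build_wgrm(z: CenteredGenotypes, w: MarkerWeights,
               ridge_eps: float = 1e-6,
               ibs_correction: str = "mean_diag") -> RelationshipMatrix:
    """Weighted genomic relationship matrix G = sum_i w_i z_i z_i'.

    The weighted sum of rank-1 single-locus matrices is normalized by the
    total weight and put on a common scale across schemes by the
    mean-identity-by-state correction: ``mean_diag`` (default) rescales so
    the mean diagonal equals 1; ``subtract_offdiag`` instead subtracts the
    mean off-diagonal element.  A diagonal ridge of ``ridge_eps`` times the
    mean diagonal keeps the matrix invertible for the mixed-model
    equations.
    """
    weights = w.w
    if weights.shape[0] != z.Z.shape[1]:
        raise ValidationError("weights do not align with markers")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("total marker weight is zero")
    wn = weights / total
    G = (z.Z * wn) @ z.Z.T
    G = 0.5 * (G + G.T)
    if ibs_correction == "mean_diag":
        md = float(np.mean(np.diag(G)))
        if md <= 0:
            raise ValidationError("mean diagonal of G is not positive")
        G /= md
    elif ibs_correction == "subtract_offdiag":
        n = G.shape[0]
        off = (G.sum() - np.trace(G)) / (n * (n - 1))
        G = G - off
        np.fill_diagonal(G, np.diag(G) + off)  # leave diagonal untouched
    else:
        raise ValueError(f"unknown ibs_correction {ibs_correction!r}")
    if ridge_eps:
        G[np.diag_indices_from(G)] += ridge_eps * float(np.mean(np.diag(G)))
    return RelationshipMatrix(z.ids, G, f"G_{w.scheme}")
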