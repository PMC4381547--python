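"""Pedigree k-medoids cross-validation of the weighting schemes.

Individuals are clustered into k folds on the pedigree-relationship
distance; each fold in turn is masked and predicted from the remaining
folds.  For the trait-specific schemes (SM, RR, BL) marker effects are
re-estimated on the training folds only, so no validation information
leaks into the weights.  Accuracy is the correlation between observed and
predicted records multiplied by the fold's mean PTA reliability (a proxy
penalty for not knowing true breeding values); bias is the ordinary
least-squares slope of observed on predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree, TraitTable, ValidationError
from .gblup import DEFAULT_H2_GRID, select_lambda, weight_phenotypes
from .grm import build_wgrm, center, marker_weights
from .markers import GibbsConfig, bl_gibbs, rr_gibbs, sm_scan
from .pedigree import FoldAssignment, build_A, kmedoids, rel_distance

__all__ = ["CVResult", "accuracy", "bias", "relative_gain", "run_cv"]


@dataclass
class CVResult:
    per_fold: pd.DataFrame    # scheme, fold, accuracy, bias, mean_rel, h2_best
    summary: pd.DataFrame     # scheme, accuracy, bias, relative_gain
    folds: FoldAssignment
    mean_effects: dict        # scheme -> per-marker effect averaged over folds
    predictions: pd.DataFrame  # id, fold, scheme, y, y_hat
    fpr: pd.DataFrame | None = None  # top-t window FPR (needs annotation)


def accuracy(y, y_hat, mean_rel: float) -> float:
    """Pearson correlation of observed and predicted records, multiplied
    by the fold's mean reliability."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if len(y) != len(y_hat) or len(y) < 3:
        raise ValidationError("accuracy needs >= 3 paired values")
    if not (0 < mean_rel <= 1):
        raise ValidationError("mean reliability outside (0,1]")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        warnings.warn("zero variance: accuracy undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(y, y_hat)[0, 1] * mean_rel)


def bias(y, y_hat) -> float:
    """OLS slope b of y = a + b * y_hat + e; 1 means dispersion-unbiased,
    > 1 means predictions are over-dispersed relative to the records."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    v = np.var(y_hat)
    if v == 0:
        warnings.warn("zero variance in predictions: bias undefined",
                      stacklevel=2)
        return np.nan
    return float(np.cov(y, y_hat, ddof=0)[0, 1] / v)


def relative_gain(acc_w: float, acc_base: float) -> float:
    """(acc_w - acc_base) / acc_base."""
    if acc_base == 0:
        raise ValidationError("baseline accuracy is zero")
    return (acc_w - acc_base) / acc_base


def _subset_trait(t: TraitTable, keep: np.ndarray) -> TraitTable:
    return TraitTable([t.ids[i] for i in keep], t.pta[keep],
                      t.reliability[keep], t.h2, depta=t.depta[keep],
                      record_weight=t.record_weight[keep])


def run_cv(trait: TraitTable, genotypes: GenotypeMatrix, pedigree: Pedigree,
           schemes=("A", "BASE", "SM", "RR", "BL"), k: int = 4,
           seed: int = 0, cfg: GibbsConfig | None = None,
           h2_grid=DEFAULT_H2_GRID, weight_mode: str = "product",
           pooled_effects: bool = False, ridge_eps: float = 1e-6,
           sm_alpha: float = 0.05, annotation=None) -> CVResult:
    """k-fold pedigree k-medoids cross-validation over relationship
    schemes.

    ``schemes`` may contain "A" (pedigree matrix baseline), "BASE", "SM",
    "RR", "BL".  ``pooled_effects=True`` estimates SM/RR/BL effects once on
    the full data instead of per training split (for sensitivity checks
    only; it leaks validation information).  Returns per-fold and
    fold-averaged accuracies/biases plus relative gains versus BASE.

    With a QTL ``annotation`` (and RR among the schemes) the result also
    carries the top-t window false-positive-rate table computed from the
    RR effects averaged over the training replicates.
    """
    if trait.depta is None:
        raise ValidationError("trait table must be de-regressed first")
    if trait.ids != list(genotypes.individual_ids):
        raise ValidationError("trait and genotype individuals must match "
                              "and be in the same order")
    cfg = cfg or GibbsConfig()
    n = len(trait)
    A_full = build_A(pedigree)
    A = A_full.subset(trait.ids)
    folds = kmedoids(rel_distance(A), k=k, seed=seed)

    y_obs = weight_phenotypes(trait, weight_mode)
    res_w = trait.record_weight if weight_mode == "residual" else None
    zc = center(genotypes)
    p = zc.p

    def chain_cfg(fold_label: int) -> GibbsConfig:
        return GibbsConfig(nu=cfg.nu, n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                           thin=cfg.thin, alpha1=cfg.alpha1,
                           seed=(cfg.seed * 131 + fold_label) % (2 ** 31))

    def estimate(scheme: str, train_idx: np.ndarray, fold_label: int):
        t_sub = _subset_trait(trait, train_idx)
        g_sub = GenotypeMatrix([genotypes.individual_ids[i]
                                for i in train_idx],
                               genotypes.calls[train_idx], genotypes.map)
        if scheme == "SM":
            return sm_scan(t_sub, g_sub, pedigree, alpha=sm_alpha)
        if scheme == "RR":
            return rr_gibbs(t_sub, g_sub, pedigree, chain_cfg(fold_label))[0]
        return bl_gibbs(t_sub, g_sub, pedigree, chain_cfg(fold_label))[0]

    pooled = {}
    if pooled_effects:
        all_idx = np.arange(n)
        for scheme in schemes:
            if scheme in ("SM", "RR", "BL"):
                pooled[scheme] = estimate(scheme, all_idx, 0)

    rows, preds = [], []
    effect_sums: dict[str, np.ndarray] = {}
    for scheme in schemes:
        for label in range(1, folds.k + 1):
            test = folds.fold_indices(label)
            train = np.setdiff1d(np.arange(n), test)
            if scheme == "A":
                K = A
            else:
                if scheme == "BASE":
                    eff = None
                elif pooled_effects:
                    eff = pooled[scheme]
                else:
                    eff = estimate(scheme, train, label)
                if eff is not None:
                    effect_sums.setdefault(scheme, np.zeros(len(p)))
                    effect_sums[scheme] += eff.effect
                mw = marker_weights(scheme if scheme != "A" else "BASE", p,
                                    effects=eff, alpha=sm_alpha)
                K = build_wgrm(zc, mw, ridge_eps=ridge_eps)
            sol, h2_best, _ = select_lambda(
                y_obs[train], train, test, y_obs[test], K, h2_grid,
                residual_weights=None if res_w is None else res_w[train])
            y_hat = sol.y_hat[test]
            mean_rel = float(trait.reliability[test].mean())
            rows.append({"scheme": scheme, "fold": label,
                         "accuracy": accuracy(y_obs[test], y_hat, mean_rel),
                         "bias": bias(y_obs[test], y_hat),
                         "mean_rel": mean_rel, "h2_best": h2_best,
                         "n_test": len(test)})
            for i, idx in enumerate(test):
                preds.append({"id": trait.ids[idx], "fold": label,
                              "scheme": scheme, "y": y_obs[idx],
                              "y_hat": y_hat[i]})

    per_fold = pd.DataFrame(rows)
    summary = (per_fold.groupby("scheme", sort=False)[["accuracy", "bias"]]
               .mean().reset_index())
    if "BASE" in summary["scheme"].values:
        acc_base = float(summary.loc[summary["scheme"] == "BASE",
                                     "accuracy"].iloc[0])
        summary["relative_gain"] = [
            relative_gain(a, acc_base) if s not in ("BASE",) else 0.0
            for s, a in zip(summary["scheme"], summary["accuracy"])]
    mean_effects = {s: v / folds.k for s, v in effect_sums.items()}
    fpr = None
    if annotation is not None and "RR" in mean_effects:
        from .scan import fpr_curve, make_windows, window_variance
        wt = window_variance(make_windows(genotypes.map), p,
                             mean_effects["RR"])
        fpr = fpr_curve(wt, annotation)
    return CVResult(per_fold, summary, folds, mean_effects,
                    pd.DataFrame(preds), fpr=fpr)
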