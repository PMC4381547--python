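"""Window-variance profiles, false-positive-rate curves and medoid
co-membership similarity between relationship matrices.

The genetic variance attributed to a genomic window is
V_n = sum_{i in window} 2 p_i (1 - p_i) u_i^2, with u_i the (replicate-
averaged) estimated allele-substitution effect.  Ranking windows by V_n
and cross-referencing against annotated QTL intervals yields a
false-positive-rate curve; clustering different relationship matrices and
comparing medoid co-membership of individual pairs quantifies how much a
weighted matrix re-traces pedigree structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MarkerMap, QTLAnnotation, ValidationError
from .pedigree import FoldAssignment, RelationshipMatrix, kmedoids, \
    rel_distance

__all__ = ["WindowTable", "make_windows", "window_variance", "fpr_curve",
           "medoid_similarity", "stratification_report", "DEFAULT_TOP_FRACTIONS"]

DEFAULT_TOP_FRACTIONS = (0.0001, 0.00025, 0.0005, 0.001, 0.0025, 0.005,
                         0.01, 0.025, 0.05, 0.10, 0.25, 0.50)


@dataclass
class WindowTable:
    chromosome: np.ndarray
    start_bp: np.ndarray          # bp mode: genomic; marker mode: index range
    stop_bp: np.ndarray
    members: list                 # marker-index array per window
    mode: str
    v: np.ndarray | None = None
    qtl_flag: np.ndarray | None = None
    rank: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"chrom": self.chromosome, "start": self.start_bp,
                            "stop": self.stop_bp,
                            "n_markers": [len(m) for m in self.members]})
        if self.v is not None:
            out["V"] = self.v
        if self.qtl_flag is not None:
            out["qtl_flag"] = self.qtl_flag
        if self.rank is not None:
            out["rank"] = self.rank
        return out


def make_windows(mm: MarkerMap, mode: str = "bp", size: int = 1_000_000,
                 step: int | None = None) -> WindowTable:
    """Windows over the marker map.

    ``bp`` mode tiles each chromosome with half-open [start, start+size)
    windows advanced by ``step`` (default: ``size``, i.e. non-overlapping
    tiles; empty windows are retained).  ``marker`` mode forms overlapping
    runs of ``size`` consecutive markers advanced by one marker.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    auto = mm.is_autosomal()
    chroms, starts, stops, members = [], [], [], []
    for c in sorted({int(x) for x in mm.chromosome[auto]}):
        idx = np.flatnonzero(auto & (mm.chromosome == c))
        idx = idx[np.argsort(mm.position_bp[idx], kind="stable")]
        pos = mm.position_bp[idx]
        if mode == "bp":
            s = step or size
            for w0 in range(0, int(pos.max()) + 1 if len(pos) else 1, s):
                sel = idx[(pos >= w0) & (pos < w0 + size)]
                chroms.append(c)
                starts.append(w0)
                stops.append(w0 + size)
                members.append(sel)
        elif mode == "marker":
            if len(idx) < size:
                continue
            for a in range(0, len(idx) - size + 1):
                sel = idx[a:a + size]
                chroms.append(c)
                starts.append(int(pos[a]))
                stops.append(int(pos[a + size - 1]) + 1)
                members.append(sel)
        else:
            raise ValueError(f"unknown window mode {mode!r}")
    return WindowTable(np.array(chroms), np.array(starts), np.array(stops),
                       members, mode)


def window_variance(wt: WindowTable, p: np.ndarray,
                    effects: np.ndarray) -> WindowTable:
    """Attach V_n = sum 2 p_i (1-p_i) u_i^2 to each window.

    ``effects`` is a per-marker effect vector, or a (replicates, m) array
    whose replicate mean is used (effects averaged across training folds,
    then squared).
    """
    u = np.asarray(effects, float)
    if u.ndim == 2:
        u = u.mean(axis=0)
    per_marker = 2.0 * p * (1.0 - p) * u ** 2
    v = np.array([per_marker[m].sum() if len(m) else 0.0
                  for m in wt.members])
    order = np.argsort(-v, kind="stable")  # ties stay in genomic order
    rank = np.empty(len(v), dtype=np.int64)
    rank[order] = np.arange(1, len(v) + 1)
    return WindowTable(wt.chromosome, wt.start_bp, wt.stop_bp, wt.members,
                       wt.mode, v=v, rank=rank, qtl_flag=wt.qtl_flag)


def annotate_windows(wt: WindowTable, ann: QTLAnnotation) -> WindowTable:
    """qtl_flag = 1 for windows overlapping at least one annotated QTL."""
    flags = np.zeros(len(wt), dtype=np.int8)
    for i in range(len(wt)):
        c = wt.chromosome[i]
        hit = ((ann.chromosome == c) & (ann.start_bp < wt.stop_bp[i])
               & (ann.stop_bp > wt.start_bp[i]))
        flags[i] = 1 if hit.any() else 0
    return WindowTable(wt.chromosome, wt.start_bp, wt.stop_bp, wt.members,
                       wt.mode, v=wt.v, rank=wt.rank, qtl_flag=flags)


def fpr_curve(wt: WindowTable, ann: QTLAnnotation | None,
              t_list=DEFAULT_TOP_FRACTIONS) -> pd.DataFrame:
    """False-positive rate of the top-t window declarations.

    Windows are ranked by descending V_n (ties broken by genomic order);
    for each fraction t the top ceil(t*N) windows are declared significant
    and FPR is the share of declared windows without an annotated QTL.
    """
    if wt.v is None:
        raise ValidationError("window variances not computed")
    if ann is None or len(ann) == 0:
        warnings.warn("empty QTL annotation: every declared window counts "
                      "as a false positive", stacklevel=2)
        flags = np.zeros(len(wt), dtype=np.int8)
    else:
        flags = annotate_windows(wt, ann).qtl_flag
    order = np.argsort(-wt.v, kind="stable")
    n = len(wt)
    rows = []
    for t in t_list:
        n_sig = int(np.ceil(t * n))
        if n_sig == 0:
            rows.append({"t": t, "n_significant": 0, "fpr": np.nan})
            continue
        top = order[:n_sig]
        fp = int((flags[top] == 0).sum())
        rows.append({"t": t, "n_significant": n_sig, "fpr": fp / n_sig})
    return pd.DataFrame(rows)


def medoid_similarity(ref: FoldAssignment, cmp: FoldAssignment,
                      denominator: str = "ref_pairs") -> float:
    """Co-membership agreement between two clusterings of the same
    individuals, ignoring cluster labels.

    ``ref_pairs`` (default): among the unordered pairs co-clustered in
    ``ref``, the fraction also co-clustered in ``cmp`` (the reference-
    conditioned reading).  ``all_pairs``: pairs co-clustered in both over
    all n(n-1)/2 pairs.
    """
    if list(ref.ids) != list(cmp.ids):
        raise ValidationError("fold assignments cover different individuals")
    la, lb = ref.labels, cmp.labels
    n = len(la)
    # contingency counts give pair counts without enumerating pairs
    cont = pd.crosstab(la, lb).to_numpy()

    def pairs(x):
        return x * (x - 1) // 2

    both = pairs(cont).sum()
    ref_pairs = pairs(cont.sum(axis=1)).sum()
    if denominator == "ref_pairs":
        if ref_pairs == 0:
            return 1.0
        return float(both / ref_pairs)
    if denominator == "all_pairs":
        return float(both / pairs(n))
    raise ValueError(f"unknown denominator {denominator!r}")


def stratification_report(A: RelationshipMatrix, G_base: RelationshipMatrix,
                          wG: RelationshipMatrix, k: int = 4,
                          seed: int = 0) -> pd.DataFrame:
    """Cluster each matrix with k-medoids on the relationship distance and
    report the pairwise medoid co-membership similarities (wG vs A, wG vs
    G_base, G_base vs A)."""
    assignments = {}
    for label, mat in (("A", A), ("G_base", G_base), ("wG", wG)):
        assignments[label] = kmedoids(rel_distance(mat), k=k, seed=seed)
    rows = []
    for ref_lab, cmp_lab in (("wG", "A"), ("wG", "G_base"), ("G_base", "A")):
        rows.append({"reference": ref_lab, "comparison": cmp_lab,
                     "similarity": medoid_similarity(assignments[ref_lab],
                                                     assignments[cmp_lab])})
    return pd.DataFrame(rows)
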