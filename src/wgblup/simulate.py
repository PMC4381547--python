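"""Synthetic sire-family pedigrees, LD-structured genotypes and traits.

The generator emulates the data structure of a progeny-tested dairy-bull
cohort: a multi-generation pedigree of paternal half-sib families, 50K-chip
style biallelic genotypes obtained by dropping founder haplotypes through
the pedigree with recombination, and de-regressed pseudo-phenotypes with
per-individual reliabilities.

Linkage disequilibrium exists only among founder haplotypes (a first-order
Markov chain along each chromosome); descendants recombine on an evenly
spaced map under Haldane's map function at 1 cM/Mb.  This is the minimal
mechanism that makes nearby markers tag a QTL, which is what the weighted
relationship matrices downstream exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (UNKNOWN_PARENT, GenotypeMatrix, MarkerMap, Pedigree,
                   TraitTable, garrick_weight)

__all__ = ["ArchitectureSpec", "TruthSet", "sim_pedigree", "sim_genotypes",
           "sim_trait", "sim_null_trait"]


@dataclass
class ArchitectureSpec:
    """Trait architecture: number of QTL, concentration of variance on the
    largest QTL, effect-size law, heritability of the pseudo-phenotype and
    the reliability distribution of the simulated records.

    When ``rel_low``/``rel_high`` are left unset the per-individual
    reliabilities are drawn around ``h2``, so that the realized genetic
    fraction of the pseudo-phenotype variance matches the target
    heritability.  Setting them explicitly (e.g. 0.85-0.95 for
    progeny-tested bulls) decouples record reliability from trait
    heritability.
    """

    n_qtl: int
    h2: float
    major_fraction: float = 0.0
    effect_distribution: str = "normal"
    rel_low: float | None = None
    rel_high: float | None = None

    def __post_init__(self) -> None:
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be non-negative")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 outside (0,1)")
        if not (0.0 <= self.major_fraction <= 1.0):
            raise ValueError("major_fraction outside [0,1]")
        if self.major_fraction == 1.0 and self.n_qtl > 1:
            raise ValueError("major_fraction=1 inconsistent with n_qtl>1")
        if self.effect_distribution not in ("normal", "gamma-signed"):
            raise ValueError(
                f"unknown effect distribution {self.effect_distribution!r}")
        if self.rel_low is None:
            self.rel_low = float(np.clip(self.h2 - 0.05, 0.21, 0.98))
        if self.rel_high is None:
            self.rel_high = float(np.clip(self.h2 + 0.05, self.rel_low + 0.005,
                                          0.99))
        if not (0.2 < self.rel_low < self.rel_high < 1.0):
            raise ValueError("reliability bounds outside (0.2, 1)")


@dataclass
class TruthSet:
    """Ground truth of a simulated trait: per-marker effects ``q``, true
    breeding values ``u = Zc q`` (Zc = genotypes centered by 2p) and the
    realized heritability var(u)/var(y)."""

    q: np.ndarray
    u: np.ndarray
    realized_h2: float
    qtl_indices: np.ndarray


def sim_pedigree(n_founders: int, n_sires: int, progeny_per_sire: int,
                 n_generations: int, seed: int) -> Pedigree:
    """Multi-generation pedigree of paternal half-sib families.

    Founders (half male, half female) have unknown parents.  In each later
    generation, ``n_sires`` males of the previous generation are drawn as
    sires; each sire produces ``progeny_per_sire`` offspring whose dams are
    drawn (with replacement) from all females born so far.
    """
    if min(n_founders, n_sires, progeny_per_sire) < 1 or n_generations < 0:
        raise ValueError("pedigree sizes must be positive")
    rng = np.random.default_rng(seed)
    ids, sires, dams = [], [], []
    males, females = [], []
    for i in range(n_founders):
        iid = f"F{i + 1:05d}"
        ids.append(iid)
        sires.append(UNKNOWN_PARENT)
        dams.append(UNKNOWN_PARENT)
        (males if i < (n_founders + 1) // 2 else females).append(iid)
    prev_males = list(males)
    counter = 0
    for gen in range(1, n_generations + 1):
        if n_sires > len(prev_males):
            raise ValueError(
                f"n_sires={n_sires} exceeds the {len(prev_males)} available "
                f"males in generation {gen - 1}")
        chosen = rng.choice(len(prev_males), size=n_sires, replace=False)
        gen_sires = [prev_males[i] for i in sorted(chosen)]
        new_males: list[str] = []
        for sire in gen_sires:
            for _ in range(progeny_per_sire):
                counter += 1
                iid = f"G{gen}I{counter:05d}"
                dam = females[rng.integers(len(females))]
                ids.append(iid)
                sires.append(sire)
                dams.append(dam)
                if rng.random() < 0.5:
                    new_males.append(iid)
                else:
                    females.append(iid)
        prev_males = new_males
    return Pedigree(np.array(ids, dtype=object),
                    np.array(sires, dtype=object),
                    np.array(dams, dtype=object))


def _founder_haplotypes(n_hap: int, freqs: np.ndarray, ld_rho: float,
                        chrom_of: np.ndarray, rng) -> np.ndarray:
    """Binary haplotypes from a first-order Markov chain per chromosome.

    Adjacent loci have allelic correlation approximately ``ld_rho``; the
    transition probabilities are clamped to [0,1], so the achieved
    correlation falls below the nominal value when adjacent allele
    frequencies differ strongly.
    """
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    u = rng.random((n_hap, m))
    hap[:, 0] = u[:, 0] < freqs[0]
    sd = np.sqrt(freqs * (1.0 - freqs))
    for j in range(1, m):
        if chrom_of[j] != chrom_of[j - 1] or ld_rho == 0.0:
            hap[:, j] = u[:, j] < freqs[j]
            continue
        c = ld_rho * sd[j - 1] * sd[j]
        p1 = np.clip(freqs[j] + c / freqs[j - 1], 0.0, 1.0)
        p0 = np.clip(freqs[j] - c / (1.0 - freqs[j - 1]), 0.0, 1.0)
        prob = np.where(hap[:, j - 1] == 1, p1, p0)
        hap[:, j] = u[:, j] < prob
    return hap


def sim_genotypes(ped: Pedigree, m: int, maf_low: float = 0.05,
                  maf_high: float = 0.5, ld_rho: float = 0.5,
                  map_length_mb: float = 100.0, seed: int = 0,
                  n_chromosomes: int = 1) -> GenotypeMatrix:
    """Gene-drop genotypes for every individual of ``ped``.

    Founders receive haplotypes from the Markov-chain model; every
    descendant inherits one gamete from each parent with Haldane
    recombination on ``n_chromosomes`` evenly covered chromosomes of
    ``map_length_mb`` Mb total (1 cM/Mb).
    """
    if m < 2 and ld_rho > 0:
        raise ValueError("ld_rho > 0 requires at least 2 markers")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho outside [0,1)")
    rng = np.random.default_rng(seed)
    n = len(ped)

    chrom_of = np.repeat(np.arange(1, n_chromosomes + 1),
                         int(np.ceil(m / n_chromosomes)))[:m]
    per_chrom_mb = map_length_mb / n_chromosomes
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, n_chromosomes + 1):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = np.linspace(0, per_chrom_mb * 1e6, len(idx),
                               endpoint=False).astype(np.int64)
    # Haldane: adjacent-interval recombination fraction at 1 cM/Mb
    d_morgan = np.diff(pos) / 1e8
    rec = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    rec[np.diff(chrom_of) != 0] = 0.5  # free recombination across chromosomes

    freqs = rng.uniform(maf_low, maf_high, size=m)
    sire_ix, dam_ix = ped.parent_indices()
    founders = np.flatnonzero((sire_ix < 0) & (dam_ix < 0))
    if len(founders) < len(ped):
        non_founder = np.flatnonzero((sire_ix >= 0) != (dam_ix >= 0))
        if len(non_founder):
            raise ValueError("individuals with exactly one known parent are "
                             "not supported by the gene-dropper")

    haps = np.zeros((n, 2, m), dtype=np.int8)
    fh = _founder_haplotypes(2 * len(founders), freqs, ld_rho, chrom_of, rng)
    haps[founders] = fh.reshape(len(founders), 2, m)

    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        if s < 0:
            continue
        for k, parent in ((0, s), (1, d)):
            switch = rng.random(m - 1) < rec
            src = np.empty(m, dtype=np.int8)
            src[0] = rng.integers(2)
            src[1:] = (src[0] + np.cumsum(switch)) % 2
            haps[i, k] = haps[parent, src, np.arange(m)]

    calls = haps.sum(axis=1).astype(np.float64)
    mm = MarkerMap(np.array([f"M{j + 1:06d}" for j in range(m)], dtype=object),
                   chrom_of.astype(object), pos)
    return GenotypeMatrix(list(ped.ids), calls, mm)


def sim_null_trait(ped: Pedigree, h2: float, seed: int = 0,
                   rel_low: float = 0.45, rel_high: float = 0.55
                   ) -> TraitTable:
    """Family-structured trait with no marker association.

    Each paternal half-sib family shares a sire effect drawn from
    N(0, h2/4) (individuals with an unknown sire draw their own), plus an
    independent residual taking the remaining variance.  Because the trait
    never touches the genotypes, any marker association arises purely from
    family structure -- the null scenario for calibrating the
    single-marker scan's type-I error at assumed heritability ``h2``.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    sigma2_s = 0.25 * h2
    fam_eff = {}
    y = np.empty(n)
    for i, sire in enumerate(ped.sires):
        key = sire if sire != UNKNOWN_PARENT else f"__self__{ped.ids[i]}"
        if key not in fam_eff:
            fam_eff[key] = rng.normal(0.0, np.sqrt(sigma2_s))
        y[i] = fam_eff[key]
    y += rng.normal(0.0, np.sqrt(1.0 - sigma2_s), size=n)
    rel = rng.uniform(rel_low, rel_high, size=n)
    return TraitTable(list(ped.ids), y * rel, rel, h2, depta=y,
                      record_weight=garrick_weight(rel, h2))


def sim_trait(g: GenotypeMatrix, spec: ArchitectureSpec,
              seed: int = 0) -> tuple[TraitTable, TruthSet]:
    """Simulate a de-regressed pseudo-phenotype with known architecture.

    QTL are sampled among the markers; effects are rescaled so the largest
    QTL explains ``major_fraction`` of the genetic variance.  The record
    for individual i is ``depta_i = u_i + eps_i`` with
    ``var(eps_i) = var(u) (1 - r2_i)/r2_i`` so that the squared correlation
    between record and breeding value has expectation ``r2_i``.
    """
    rng = np.random.default_rng(seed)
    n, m = g.calls.shape
    if spec.n_qtl > m:
        raise ValueError("more QTL than markers")
    p = g.allele_freq()
    zc = g.calls - 2.0 * p

    q = np.zeros(m)
    if spec.n_qtl > 0:
        qtl = rng.choice(m, size=spec.n_qtl, replace=False)
        if spec.effect_distribution == "normal":
            eff = rng.standard_normal(spec.n_qtl)
        else:  # gamma-signed: heavy-tailed magnitudes with random sign
            eff = rng.gamma(0.4, 1.0, size=spec.n_qtl)
            eff *= rng.choice((-1.0, 1.0), size=spec.n_qtl)
        if spec.n_qtl > 1 and spec.major_fraction > 0:
            major = qtl[np.argmax(np.abs(eff) * np.sqrt(2 * p[qtl] *
                                                        (1 - p[qtl])))]
            minor_mask = qtl != major
            u_minor = zc[:, qtl[minor_mask]] @ eff[minor_mask]
            u_major = zc[:, major] * eff[qtl == major][0]
            vmin, vmaj = np.var(u_minor), np.var(u_major)
            f = spec.major_fraction
            if f < 1.0 and vmaj > 0 and vmin > 0:
                scale = np.sqrt((f / (1.0 - f)) * vmin / vmaj)
                eff[qtl == major] *= scale
        q[qtl] = eff
    else:
        qtl = np.array([], dtype=np.int64)

    u = zc @ q
    var_u = float(np.var(u))
    rel = rng.uniform(spec.rel_low, spec.rel_high, size=n)
    eps = rng.standard_normal(n) * np.sqrt(var_u * (1.0 - rel) / rel
                                           if var_u > 0 else 1.0)
    depta = u + eps
    var_y = float(np.var(depta))
    pta = depta * rel
    weights = garrick_weight(rel, spec.h2)
    trait = TraitTable(list(g.individual_ids), pta, rel, spec.h2,
                       depta=depta, record_weight=weights)
    truth = TruthSet(q=q, u=u,
                     realized_h2=var_u / var_y if var_y > 0 else 0.0,
                     qtl_indices=np.sort(qtl))
    return trait, truth
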