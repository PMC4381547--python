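"""Per-marker effect estimation: single-marker scan, Bayesian Ridge
Regression (RR) and Bayesian LASSO (BL).

All three estimators fit de-regressed pseudo-phenotypes with record weights
entering the residual precision (var(e_i) = sigma2_e / w_i) and correct for
population stratification with a pedigree-structured random effect:

* ``sm_scan`` fits one marker at a time as a fixed effect next to a random
  sire effect s ~ N(0, A sigma2_s) and reports the marker's F-test p-value;
  markers with p < alpha receive selection indicator S = 1.
* ``rr_gibbs`` fits all markers jointly with a common normal prior
  u ~ N(0, I sigma2_u) plus an individual polygenic effect
  a ~ N(0, A sigma2_a); variances carry scaled-inverse-chi-squared priors.
* ``bl_gibbs`` replaces the common normal prior by the double-exponential
  (Laplace) prior via the exponential scale mixture: u_j ~ N(0, tau2_j
  sigma2_e), tau2_j ~ Exp(lambda2/2), lambda2 ~ Gamma(alpha1, rate alpha2).

Prior scales follow the expected-variance calibration: with trait variance
V_y, heritability h2 and prior degrees of freedom nu,
S_a = V_y (h2/2)(nu-2), S_e = V_y (1-h2)(nu-2), and the marker-variance
scale S_RR = S_a / MS_w where MS_w is the per-individual sum of squared
genotype deviations from marker means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import linalg, stats

from .data import GenotypeMatrix, Pedigree, TraitTable, ValidationError
from .pedigree import build_A

__all__ = ["GibbsConfig", "MarkerEffects", "ChainSummary", "ms_w",
           "prior_scales", "bl_hyperparams", "sm_scan", "rr_gibbs",
           "bl_gibbs"]


@dataclass
class MarkerEffects:
    marker_id: np.ndarray
    effect: np.ndarray
    method: str                        # "SM", "RR" or "BL"
    p_value: np.ndarray | None = None  # SM only
    indicator: np.ndarray | None = None
    posterior_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.effect)):
            raise ValidationError("non-finite marker effect")
        if self.p_value is not None and (np.any(self.p_value < 0)
                                         or np.any(self.p_value > 1)):
            raise ValidationError("p-value outside [0,1]")


@dataclass
class ChainSummary:
    """Posterior summaries of the variance components, computed from
    post-burn-in thinned samples only.  ``split_ratio`` compares first- and
    second-half posterior means per parameter (values near 1 suggest the
    chain mixed)."""

    posterior_mean: dict
    posterior_sd: dict
    split_ratio: dict
    n_samples: int


@dataclass
class GibbsConfig:
    """Chain settings and hyper-parameters for the Gibbs samplers.

    Defaults are the long production chain (120 000 sweeps, 20 000 burn-in,
    thinning 10, nu = 5, alpha1 = 1.01); analyses on small simulated data
    use much shorter chains.
    """

    nu: float = 5.0
    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    alpha1: float = 1.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2 (scales use nu - 2)")


def ms_w(g: GenotypeMatrix | np.ndarray) -> float:
    """Per-individual sum of squared genotype deviations from marker means:
    MS_w = n^-1 sum_i sum_j (x_ij - xbar_j)^2."""
    calls = g.calls if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    if calls.size == 0:
        raise ValidationError("empty genotype matrix")
    dev = calls - calls.mean(axis=0)
    return float((dev * dev).sum() / calls.shape[0])


def prior_scales(v_y: float, h2: float, nu: float,
                 ms_w_value: float) -> tuple[float, float, float]:
    """Scales (S_a, S_e, S_RR) of the scaled-inverse-chi-squared priors.

    Calibrated so the prior means equal the expected variance components:
    E[sigma2] = S/(nu-2) gives E[sigma2_a] = V_y h2/2 (half the genetic
    variance to the polygenic term, half to markers), E[sigma2_e] =
    V_y (1-h2), and E[sigma2_u] = V_y (h2/2) / MS_w.
    """
    if nu <= 2:
        raise ValueError("nu must exceed 2")
    if v_y <= 0 or not (0 < h2 < 1) or ms_w_value <= 0:
        raise ValueError("need v_y > 0, 0 < h2 < 1, ms_w > 0")
    s_a = v_y * 0.5 * h2 * (nu - 2.0)
    s_e = v_y * (1.0 - h2) * (nu - 2.0)
    s_rr = s_a / ms_w_value
    return s_a, s_e, s_rr


def bl_hyperparams(h2: float, ms_w_value: float,
                   alpha1: float = 1.01) -> tuple[float, float]:
    """Gamma hyper-prior (shape alpha1, rate alpha2) for the LASSO lambda2.

    alpha2 = (alpha1 - 1) h2 / (2 (1-h2) MS_w), which anchors
    sqrt((alpha1-1)/alpha2) at the target regularization
    lambda = sqrt(2 ((1-h2)/h2) MS_w).  (Note the Gamma mean is
    alpha1/alpha2, slightly above this anchor; the anchor uses alpha1 - 1.)
    """
    alpha2 = (alpha1 - 1.0) * h2 / (2.0 * (1.0 - h2) * ms_w_value)
    lam_anchor = np.sqrt(2.0 * (1.0 - h2) / h2 * ms_w_value)
    return alpha2, lam_anchor


# ---------------------------------------------------------------------------
# single-marker scan
# ---------------------------------------------------------------------------


def _align(t: TraitTable, g: GenotypeMatrix):
    """Row indices of the genotype matrix for each phenotyped individual."""
    pos = {i: k for k, i in enumerate(g.individual_ids)}
    missing = [i for i in t.ids if i not in pos]
    if missing:
        raise ValidationError(f"phenotyped individuals without genotypes: "
                              f"{missing[:5]}")
    return np.array([pos[i] for i in t.ids], dtype=np.intp)


def sm_scan(t: TraitTable, g: GenotypeMatrix, ped: Pedigree,
            alpha: float = 0.05, bonferroni: bool = False,
            sire_h2: float | None = None) -> MarkerEffects:
    """Single-marker fixed-effect scan with a random sire effect.

    Model per marker: y = 1 b0 + x b + Z_s s + e/w with s ~ N(0, A_s
    sigma2_s) over the sires of the phenotyped individuals.  The sire
    variance is fixed at sigma2_s = (h2/4) var(y) (a quarter of the
    additive variance passes through the sire) and the residual takes the
    remainder, so each marker costs one generalized-least-squares solve.
    The marker's 1-df F statistic is referred to F(1, n-2); markers with
    p < alpha (strict) get indicator S = 1.  Monomorphic markers get
    p = 1, S = 0.  Individuals with an unknown sire form singleton sire
    groups unrelated to every other group.
    """
    if t.depta is None:
        raise ValidationError("trait table must be de-regressed first")
    h2 = t.h2 if sire_h2 is None else sire_h2
    row = _align(t, g)
    X = g.calls[row]
    y = t.depta
    w = t.record_weight
    n, m = X.shape

    pos = {i: k for k, i in enumerate(ped.ids)}
    sire_of = []
    for iid in t.ids:
        if iid not in pos:
            raise ValidationError(f"phenotyped individual {iid!r} absent "
                                  f"from pedigree")
        s = ped.sires[pos[iid]]
        # unknown sire: the individual forms its own singleton sire group
        sire_of.append(s if s != "0" else f"__self__{iid}")
    sires = sorted(set(sire_of))
    s_idx = {s: k for k, s in enumerate(sires)}
    zs = np.zeros((n, len(sires)))
    zs[np.arange(n), [s_idx[s] for s in sire_of]] = 1.0

    v_y = float(np.var(y))
    sigma2_s = 0.25 * h2 * v_y
    sigma2_e = max(v_y - sigma2_s, 1e-8 * v_y)
    real = [s for s in sires if not s.startswith("__self__")]
    A_s = np.eye(len(sires))
    if real:
        sub = build_A(ped).subset(real).values
        rix = np.array([s_idx[s] for s in real], dtype=np.intp)
        A_s[np.ix_(rix, rix)] = sub
    V = sigma2_s * (zs @ A_s @ zs.T) + np.diag(sigma2_e / w)
    cf = linalg.cho_factor(V, lower=True)
    vi_one = linalg.cho_solve(cf, np.ones(n))
    vi_y = linalg.cho_solve(cf, y)
    vi_X = linalg.cho_solve(cf, X)

    s11 = float(np.ones(n) @ vi_one)
    s1y = float(y @ vi_one)
    s1x = X.T @ vi_one
    sxy = X.T @ vi_y
    sxx = np.einsum("ij,ij->j", X, vi_X)

    det = s11 * sxx - s1x * s1x
    mono = X.var(axis=0) == 0.0
    safe = np.where(det > 1e-12 * s11 * np.maximum(sxx, 1e-300), det, np.nan)
    b = (s11 * sxy - s1x * s1y) / safe
    f_stat = b * b * safe / s11
    p = stats.f.sf(f_stat, 1, max(n - 2, 1))
    p[mono | ~np.isfinite(p)] = 1.0
    b[~np.isfinite(b)] = 0.0

    thr = alpha / m if bonferroni else alpha
    indicator = (p < thr).astype(np.int8)
    return MarkerEffects(g.map.marker_id, b, "SM", p_value=p,
                         indicator=indicator)


# ---------------------------------------------------------------------------
# Gibbs samplers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rinvgauss(mu, lam):
    v = np.random.normal() ** 2
    x = mu + (mu * mu * v) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v)
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _gibbs_kernel(Xt, y, w, Ainv, s_a, s_e, s_u, nu, n_iter, burn_in, thin,
                  seed, lasso, alpha1, alpha2, lambda2_fixed):
    """Single-site Gibbs chain shared by RR and BL.

    Xt is the (m, n) transposed dosage matrix.  Returns a status code
    (0 = ok, otherwise the 1-based sweep at which a non-finite draw was
    detected) plus posterior accumulators for the marker effects and the
    kept samples of (sigma2_u-or-lambda2, sigma2_a, sigma2_e).
    """
    np.random.seed(seed)
    m, n = Xt.shape

    sw = 0.0
    ymean = 0.0
    for i in range(n):
        sw += w[i]
        ymean += w[i] * y[i]
    ymean /= sw

    mu = ymean
    u = np.zeros(m)
    a = np.zeros(n)
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu
    t_vec = np.zeros(n)

    xwx = np.empty(m)
    for j in range(m):
        acc = 0.0
        for i in range(n):
            acc += w[i] * Xt[j, i] * Xt[j, i]
        xwx[j] = acc

    sigma_e = s_e / (nu - 2.0)
    sigma_a = s_a / (nu - 2.0)
    sigma_u = s_u / (nu - 2.0) if s_u > 0.0 else 1.0
    if lasso and lambda2_fixed > 0.0:
        lambda2 = lambda2_fixed
    elif lasso:
        lambda2 = (alpha1 - 1.0) / alpha2
    else:
        lambda2 = 1.0
    tau2 = np.full(m, 2.0 / lambda2 if lasso else 1.0)

    n_kept = (n_iter - burn_in + thin - 1) // thin
    u_sum = np.zeros(m)
    u_sq = np.zeros(m)
    var_samples = np.zeros((n_kept, 3))
    kept = 0

    for it in range(1, n_iter + 1):
        # population mean (flat prior)
        swe = 0.0
        for i in range(n):
            swe += w[i] * e[i]
        mu_new = np.random.normal(mu + swe / sw, np.sqrt(sigma_e / sw))
        d_mu = mu_new - mu
        for i in range(n):
            e[i] -= d_mu
        mu = mu_new

        # marker effects
        for j in range(m):
            rhs = 0.0
            for i in range(n):
                rhs += w[i] * Xt[j, i] * e[i]
            rhs += xwx[j] * u[j]
            if lasso:
                prior_prec = 1.0 / tau2[j]
            else:
                prior_prec = sigma_e / sigma_u
            c = xwx[j] + prior_prec
            unew = np.random.normal(rhs / c, np.sqrt(sigma_e / c))
            diff = unew - u[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Xt[j, i] * diff
            u[j] = unew

        # polygenic effect, single-site with A-inverse prior
        for i in range(n):
            old = a[i]
            aii = Ainv[i, i]
            prior_mean = old - t_vec[i] / aii
            prior_prec = aii / sigma_a
            lik_prec = w[i] / sigma_e
            post_prec = prior_prec + lik_prec
            post_mean = (prior_mean * prior_prec
                         + (e[i] + old) * lik_prec) / post_prec
            anew = np.random.normal(post_mean, np.sqrt(1.0 / post_prec))
            diff = anew - old
            if diff != 0.0:
                e[i] -= diff
                for r in range(n):
                    t_vec[r] += Ainv[r, i] * diff
                a[i] = anew
        if it % 1000 == 0:  # refresh against incremental drift
            for r in range(n):
                acc = 0.0
                for c2 in range(n):
                    acc += Ainv[r, c2] * a[c2]
                t_vec[r] = acc

        # variance components
        sse = 0.0
        for i in range(n):
            sse += w[i] * e[i] * e[i]
        sigma_e = (s_e + sse) / np.random.chisquare(nu + n)
        saa = 0.0
        for i in range(n):
            saa += a[i] * t_vec[i]
        if saa < 0.0:
            saa = 0.0
        sigma_a = (s_a + saa) / np.random.chisquare(nu + n)

        if lasso:
            sum_tau = 0.0
            for j in range(m):
                uj2 = u[j] * u[j]
                floor = 1e-10 * sigma_e
                if uj2 < floor:
                    uj2 = floor
                mu_ig = np.sqrt(lambda2 * sigma_e / uj2)
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_tau = _rinvgauss(mu_ig, lambda2)
                tau2[j] = 1.0 / inv_tau
                sum_tau += tau2[j]
            if lambda2_fixed <= 0.0:
                lambda2 = np.random.gamma(alpha1 + m,
                                          1.0 / (alpha2 + 0.5 * sum_tau))
        else:
            ssu = 0.0
            for j in range(m):
                ssu += u[j] * u[j]
            sigma_u = (s_u + ssu) / np.random.chisquare(nu + m)

        if not (np.isfinite(sigma_e) and np.isfinite(sigma_a)
                and np.isfinite(mu)):
            return it, u_sum, u_sq, kept, var_samples

        if it > burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                u_sum[j] += u[j]
                u_sq[j] += u[j] * u[j]
            var_samples[kept, 0] = lambda2 if lasso else sigma_u
            var_samples[kept, 1] = sigma_a
            var_samples[kept, 2] = sigma_e
            kept += 1

    return 0, u_sum, u_sq, kept, var_samples


def _prep_gibbs(t: TraitTable, g: GenotypeMatrix, ped: Pedigree):
    if t.depta is None:
        raise ValidationError("trait table must be de-regressed first")
    row = _align(t, g)
    X = np.ascontiguousarray(g.calls[row].T)  # (m, n)
    y = t.depta.astype(np.float64)
    w = t.record_weight.astype(np.float64)
    A = build_A(ped).subset(t.ids).values
    Ainv = np.linalg.inv(A)
    Ainv = 0.5 * (Ainv + Ainv.T)
    return X, y, w, Ainv


def _summarize(var_samples, kept, labels):
    vs = var_samples[:kept]
    half = kept // 2
    mean = {lab: float(vs[:, i].mean()) for i, lab in enumerate(labels)}
    sd = {lab: float(vs[:, i].std()) for i, lab in enumerate(labels)}
    ratio = {}
    for i, lab in enumerate(labels):
        m2 = vs[half:, i].mean()
        ratio[lab] = float(vs[:half, i].mean() / m2) if m2 != 0 else np.nan
    return ChainSummary(mean, sd, ratio, int(kept))


def rr_gibbs(t: TraitTable, g: GenotypeMatrix, ped: Pedigree,
             cfg: GibbsConfig) -> tuple[MarkerEffects, ChainSummary]:
    """Bayesian Ridge Regression of all markers with a pedigree polygenic
    effect; returns posterior-mean effects and a chain summary."""
    X, y, w, Ainv = _prep_gibbs(t, g, ped)
    v_y = float(np.var(y)) or 1.0  # unit fallback for a constant phenotype
    s_a, s_e, s_rr = prior_scales(v_y, t.h2, cfg.nu, ms_w(g.calls[_align(t, g)]))
    status, u_sum, u_sq, kept, vs = _gibbs_kernel(
        X, y, w, Ainv, s_a, s_e, s_rr, cfg.nu, cfg.n_iter, cfg.burn_in,
        cfg.thin, cfg.seed, False, cfg.alpha1, 1.0, 0.0)
    if status != 0:
        raise FloatingPointError(f"RR chain diverged at sweep {status}")
    u_mean = u_sum / kept
    u_sd = np.sqrt(np.maximum(u_sq / kept - u_mean ** 2, 0.0))
    eff = MarkerEffects(g.map.marker_id, u_mean, "RR", posterior_sd=u_sd)
    return eff, _summarize(vs, kept, ("sigma2_u", "sigma2_a", "sigma2_e"))


def bl_gibbs(t: TraitTable, g: GenotypeMatrix, ped: Pedigree,
             cfg: GibbsConfig,
             lambda2_fixed: float | None = None
             ) -> tuple[MarkerEffects, ChainSummary]:
    """Bayesian LASSO of all markers (double-exponential prior via the
    exponential scale mixture) with a pedigree polygenic effect.

    ``lambda2_fixed`` pins the regularization parameter instead of
    sampling it from its gamma hyper-prior (useful for sensitivity
    analyses of the shrinkage intensity).
    """
    X, y, w, Ainv = _prep_gibbs(t, g, ped)
    row = _align(t, g)
    v_y = float(np.var(y)) or 1.0  # unit fallback for a constant phenotype
    msw = ms_w(g.calls[row])
    s_a, s_e, _ = prior_scales(v_y, t.h2, cfg.nu, msw)
    alpha2, _ = bl_hyperparams(t.h2, msw, cfg.alpha1)
    status, u_sum, u_sq, kept, vs = _gibbs_kernel(
        X, y, w, Ainv, s_a, s_e, 0.0, cfg.nu, cfg.n_iter, cfg.burn_in,
        cfg.thin, cfg.seed, True, cfg.alpha1, alpha2,
        0.0 if lambda2_fixed is None else float(lambda2_fixed))
    if status != 0:
        raise FloatingPointError(f"BL chain diverged at sweep {status}")
    u_mean = u_sum / kept
    u_sd = np.sqrt(np.maximum(u_sq / kept - u_mean ** 2, 0.0))
    eff = MarkerEffects(g.map.marker_id, u_mean, "BL", posterior_sd=u_sd)
    return eff, _summarize(vs, kept, ("lambda2", "sigma2_a", "sigma2_e"))
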