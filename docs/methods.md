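# Methods

## Problem and model

`wgblup` predicts additive genetic merit (breeding values) for genotyped
individuals from de-regressed pseudo-phenotypes, using genomic BLUP with a
relationship matrix whose per-marker contributions are weighted by the
trait's architecture.  Standard GBLUP assumes every marker contributes
equally to genetic variance; for traits governed by few or large-effect
QTL that assumption is violated, and re-weighting markers by their
estimated contribution can recover accuracy and reduce dispersion bias.

The chain of models is:

1. **De-regression.**  A predicted transmitting ability (PTA) with
   reliability r² is converted to a pseudo-record dePTA = PTA / r² with a
   Garrick-style record weight w = (1−h²) / ((c + (1−r²)/r²) h²), default
   c = 0.5.  The single-record form is used (no parent-average removal);
   under this form the de-regressed record is a rescaling of the PTA, so
   its reliability equals the PTA reliability and the retention filter
   (reliability > 0.2, strict) is unambiguous.  Records enter downstream
   models either pre-multiplied by their weight ("product" mode, the
   default) or with the weight in the residual precision ("residual"
   mode).

2. **Marker effects**, three ways, all including a pedigree-structured
   random effect against population stratification:
   * **SM** — per-marker fixed-effect scan with a random sire effect
     s ~ N(0, A_s σ²_s).  σ²_s is fixed at (h²/4)·var(y) rather than
     re-estimated per marker, so the scan is one generalized
     least-squares solve per marker; the 1-df Wald F is referred to
     F(1, n−2).  Markers with p < 0.05 (strict) get indicator S = 1.  No
     multiple-testing correction by default (a Bonferroni switch exists).
     Individuals with unknown sires form singleton phantom sire groups.
   * **RR** — Bayesian ridge: all markers jointly, u ~ N(0, I σ²_u),
     polygenic a ~ N(0, A σ²_a), variances with scaled-inverse-χ²(ν, S)
     priors.  Scales are calibrated from the phenotypic variance V_y and
     heritability: S_a = V_y (h²/2)(ν−2), S_e = V_y (1−h²)(ν−2),
     S_RR = S_a / MS_w, where MS_w = n⁻¹ Σᵢ Σⱼ (x_ij − x̄_j)² summarizes
     genotype variability; ν = 5.
   * **BL** — Bayesian LASSO via the exponential scale mixture:
     u_j ~ N(0, τ²_j σ²_e), τ²_j ~ Exp(λ²/2), λ² ~ Gamma(α₁, rate α₂)
     with α₁ = 1.01 and α₂ = (α₁−1) h² / (2(1−h²) MS_w), anchoring
     √((α₁−1)/α₂) at λ = √(2 ((1−h²)/h²) MS_w).  Note this anchor is not
     the Gamma mean √(α₁/α₂); the printed calibration is implemented
     as-is and the (tiny, since α₁ ≈ 1) discrepancy left unresolved.

   Both samplers are single-site Gibbs chains compiled with numba.  The
   polygenic effect is updated site-by-site from the dense A⁻¹ (with an
   incremental A⁻¹a cache refreshed every 1000 sweeps against float
   drift).  Default chain: 120 000 sweeps, 20 000 burn-in, thinning 10;
   every analysis in the test-suite uses much shorter chains
   (6000/1000/5 or less) with tolerance set by Monte-Carlo error, not
   fixed decimals.  Marker covariates enter as raw 0/1/2 dosages; the
   sampled mean absorbs the offset.

3. **Weighted GRM.**  Dosages are centered by twice the counted-allele
   frequency of the analysis cohort, z_ij = x_ij − 2p_j, and
   G = Σ_i w_i z_i z_i′ / Σ w_i with scheme weights
   w_i = 2p_i(1−p_i) (BASE), ×S_i (SM), ×û_i² (RR/BL).  The
   "mean-IBS" correction is implemented as mean-diagonal standardization
   (rescale so mean(diag G) = 1), putting all schemes on a common scale;
   the alternative of subtracting the mean off-diagonal is available
   behind a flag.  A configurable diagonal ridge (default 10⁻⁶ of the
   mean diagonal) keeps G numerically invertible where needed.

4. **GBLUP.**  The mixed-model equations with variance ratio
   λ = (1−h²)/h² are solved in the absorbed variance form
   V = Z G Z′ + λR, μ̂ = (1′V⁻¹y)/(1′V⁻¹1), û = G Z′V⁻¹(y − 1μ̂) — 
   algebraically identical to inverting the G⁻¹ block system but defined
   for merely positive-semidefinite G.  This matters because a
   centered-genotype G is exactly singular (G·1 = 0), and it is what
   makes the SNP-BLUP equivalence tests exact at ridge 0.  Masked
   individuals have no record rows and are predicted purely through the
   relationship coupling.  λ is selected on the heritability grid
   0.1…0.9 (step 0.1) by minimizing d = Σ|y_i − ŷ_i| over the masked
   records; the literal signed sum is available behind a flag but is a
   degenerate objective (it rewards unbounded over-prediction), so the
   absolute version is the default.

5. **Cross-validation.**  Individuals are clustered into k = 4 folds by
   PAM k-medoids on the pedigree distance d_ij = 1 − a_ij/√(a_ii a_jj).
   PAM uses a deterministic greedy build phase plus best-improvement
   swaps; the seed only breaks exact ties, and nearest-medoid ties go to
   the lowest medoid index.  For SM/RR/BL the marker effects are
   re-estimated inside each training split (no leakage; a pooled switch
   exists for sensitivity analysis).  Accuracy is the Pearson correlation
   of observed and predicted records multiplied by the fold's mean PTA
   reliability (the multiplicative reading is the one consistent with
   low-reliability traits showing reduced accuracy); bias is the OLS
   slope of observed on predicted; both are averaged arithmetically over
   folds; relative gain is (acc − acc_BASE)/acc_BASE.

6. **Stratification diagnostics.**  Window variance
   V_n = Σ 2p_i(1−p_i)û_i² over 1-Mb windows (non-overlapping tiles by
   default, step configurable; 10-marker moving windows in "marker"
   mode), with û averaged over training replicates before squaring.
   Windows ranked by V_n give a false-positive-rate curve against an
   annotation of reported QTL (FPR = declared windows without a QTL /
   declared windows; ties broken by genomic order).  Matrix similarity is
   medoid co-membership: among pairs co-clustered under the reference
   matrix, the fraction also co-clustered under the comparison
   (reference-conditioned; an all-pairs denominator is available behind a
   flag — published values cannot adjudicate the two readings without the
   original data).  RR effects are the default input to both diagnostics.

## Synthetic data

The generator emulates a progeny-tested dairy-cattle cohort:

* **Pedigree** — founders (half male), then successive generations of
  paternal half-sib families: n_sires males sire progeny_per_sire
  offspring each; dams are drawn from all females born so far.
* **Genotypes** — founder haplotypes from a first-order Markov chain with
  adjacent-locus allelic correlation ld_rho (default 0.5–0.6 in the
  analyses here) and per-locus frequencies uniform on [0.05, 0.5];
  descendants by gene dropping with Haldane recombination on an evenly
  spaced map at 1 cM/Mb.  Transition probabilities are clamped to [0,1],
  so the achieved LD falls below nominal when adjacent frequencies differ
  strongly.
* **Traits** — QTL sampled among markers with normal or signed-gamma
  effects; the largest QTL is rescaled so it carries ``major_fraction``
  of the genetic variance; records are dePTA-like: y_i = u_i + ε_i with
  var(ε_i) = var(u)(1−r²_i)/r²_i so the squared correlation of record
  and breeding value has expectation r²_i.  Because the record noise is
  driven entirely by reliability, the realized heritability of the
  records equals the mean reliability; the default reliability
  distribution is therefore uniform(h²−0.05, h²+0.05) (clipped to
  (0.2, 1)) so that simulated records realize the target h², while an
  explicit reliability range (e.g. 0.85–0.95, typical of progeny-tested
  bulls) decouples the two.  A family-structured null trait
  (``sim_null_trait``) with no marker association calibrates the scan's
  type-I error.

What the generator does **not** reproduce: coalescent-realistic LD decay,
selection and drift across generations, genotyping error, the
parent-average component of real de-regressed proofs, and multi-trait
correlation structure.  Passing tests therefore demonstrate internal
consistency and the qualitative architecture-dependence of the weighting
schemes, not performance magnitudes on real 50K dairy data.

## Problem sizes in the test suite

The published analysis ran on 4865 bulls × 39 004 SNP with 120 000-sweep
chains; the test suite and acceptance script use scaled-down analogues
chosen once: cross-validation comparisons on 600 individuals × 1200
markers (10 replicate seeds, chains 6000/1000/5), type-I calibration on
500 × 2000, sampler recovery on 500 × 1000, stratification on 400 × 800,
and oracle equivalences on 200 × 500.  At these sizes the few-QTL
accuracy gain of the RR-weighted matrix (mean relative gain ≈ 0.3–0.4)
is larger than the published FP gain (0.237), as expected when the
validation records are noisier and the baseline accuracy lower.

## Numerical choices and edge cases

* Tabular A-matrix construction over the topologically sorted pedigree;
  verified against an independent recursive-kinship oracle at 1e−10.
* Relationship distances are clipped below at 0 for genomic matrices
  whose off-diagonals exceed the geometric mean of the diagonals.
* Monomorphic markers: centered column becomes constant (flagged);
  in the scan they get p = 1, S = 0 rather than an exception.
* Mode imputation breaks ties toward the smaller genotype and records
  an imputation mask; it uses no linkage information.
* A constant (zero-variance) phenotype falls back to unit variance in
  the prior scales, leaving a proper symmetric posterior around zero.
* Gibbs chains abort with the sweep index if a non-finite draw appears.
* All randomness flows from explicit integer seeds; chains, fold
  assignments and simulations are bit-reproducible.

## Known limitations

* The best-fit λ grid tends to select heavier shrinkage for sharply
  weighted matrices under the absolute-deviation criterion, which pushes
  the slope of observed on predicted slightly above 1; at the test-suite
  scale the base matrix is not strongly over-dispersed (slopes near 1
  rather than the published 1.3–1.7), so the published bias-reduction
  ordering does not reproduce reliably and the corresponding acceptance
  check is expected to fail at this scale.
* PAM is a local search: globally optimal on structured family blocks,
  but on arbitrary dissimilarities it can stop within a few percent of
  the optimum.
* The single-marker scan uses fixed variance components; its p-values
  are Wald-type, exact only as n grows.
* With ``pooled_effects=True`` the CV intentionally reuses full-data
  marker effects (information leakage) for sensitivity analysis only.
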