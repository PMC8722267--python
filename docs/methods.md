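# Methods

`littervar` quantifies the genetic control of *variability* in pig litter
size (TNB, total number born): not whether a sow has large litters, but how
uniform her litters are across parities. Two established routes to a
variability phenotype are implemented side by side, together with the
machinery needed to compare them and to map variance QTL (vQTL).

## The exponential variance model

Both routes assume the residual variance of a Gaussian repeatability model
is itself under genetic control, through an exponential (log-linear) model:

    y_ij = mu + fixed_ij + u_i + pe_i + exp(0.5 (eta + v_i + pe_v,i)) eps_ij

with `u` the additive effect on the mean, `v` the additive effect on the log
residual variance, `pe`/`pe_v` the corresponding sow permanent-environment
effects, and `eps` standard normal. `(u, v)` follows a bivariate normal
with covariance `G0 (x) A` (A the pedigree numerator relationship matrix);
`(pe, pe_v)` is i.i.d. bivariate normal across sows. The genetic
correlation `r(a, a_v)` couples mean and variability; the permanent-
environment correlation `r(pe, pe_v)` does the same at the non-genetic sow
level.

## Track 1: LnVar (log-transformed variance of residuals)

1. Fit the TNB repeatability animal model (fixed herd-year-season and
   parity; additive + permanent-environment random; homogeneous residual)
   by REML and keep per-record residuals.
2. For every sow with at least two records, LnVar = log of the sample
   variance (n-1 denominator; the source is silent, unbiasedness argues for
   n-1) of her residuals. Sows with exactly zero variance are excluded
   (measure-zero with continuous data).
3. Analyse LnVar with an additive-only animal model whose fixed effect is
   the farm-year-season of the sow's first farrowing (derived as the
   herd-year-season code of her earliest-parity record) and whose residual
   variance differs between nine record-count groups (2, 3, ..., 9, and 10+
   litters), since a variance estimated from more records is less noisy.

The additive variance of this model, `sigma2_avar`, summarizes genetic
control of variability; its scale-free form is the genetic coefficient of
variation of the residual SD, `GCV_SDe = 0.5 * sqrt(sigma2_avar)`.

## Track 2: DHGLM (double hierarchical GLM)

The DHGLM couples the mean model and a variance model in one bivariate
system: trait 1 is TNB, trait 2 is a per-record working response `psi` for
the log residual variance. Both traits share the additive (2x2 `G0 (x) A`)
and permanent-environment (2x2, identity across sows) covariance
structures; residuals are independent with weights

    W   = diag(exp(psi_hat))^-1      (mean part)
    W_v = diag((1 - h) / 2)          (variance part)

where `h` is the mean-part leverage (hat-matrix diagonal) and `psi_hat` the
predicted log residual variance from the previous cycle. The scaling
variances attached to `W^-1` and `W_v^-1` are free parameters.

**Working response.** `psi` is the linearized log-link response of a gamma
GLM for the leverage-corrected squared residual `d = e^2/(1-h)`:

    psi = zeta_hat + (d - exp(zeta_hat)) / exp(zeta_hat)

with `zeta_hat` the current predicted log residual variance. Its
conditional variance is what `W_v` reciprocates. A pure `log d` response
was rejected: its mean is offset by E[log chi2_1] = -1.27 and its variance
(pi^2/2) is incompatible with `W_v`, which destabilizes the early cycles
and biases the scaling variance. At initialization `zeta_hat` is the
homoscedastic REML estimate, so a record whose `d` equals that estimate
starts at `psi = log d` exactly.

**Iteration.** Each cycle re-fits the joint system by AI-REML (2 inner
iterations, warm-started), refreshes `zeta_hat` with under-relaxation
(damping 0.7; the raw reweighting map has a mild two-cycle oscillation),
and recomputes `psi`, `W`, `W_v`. Convergence requires the largest relative
variance-component change below 1e-4 (components a thousandfold below the
dominant one are measured on the dominant scale, so a variance pinned at
the zero boundary cannot block convergence) and correlation above
1 - 1e-8 between successive variance-part EBV vectors. Both tolerances are
options. Divergence (|psi| > 50) aborts with a diagnostic.

**Scaling variances.** The mean-part scaling converges to ~1.0. The
variance-part scaling converges to ~mean(1-h), not 1: with Gaussian data
the variance of `d` is 2 exp(2 zeta), while `W_v` assumes 2 exp(2 zeta)/(1-h).
At desk scale (5-8 records per sow) mean leverage is ~0.2 and the
variance-part scaling lands near 0.8; the same behaviour is visible in the
source study, whose variance-part residual variance printed as 0.84.

The variance-part EBV `a_v` ("varTNB") is the second variability phenotype.

## Core engine: sparse AI-REML

Henderson's mixed-model equations are assembled sparsely for any number of
random terms with covariance `G0 (x) K` (K given by its sparse inverse:
pedigree A-inverse by Henderson's rules with Meuwissen-Luo inbreeding, or
identity) and a diagonal residual with free per-group variances and known
per-record weights. A SuperLU factorization provides solutions, the
log-determinant, and (column-wise) the inverse coefficient matrix, from
which prediction error variances, hat leverages and the exact REML gradient
traces follow. Updates are average-information steps with a trust region
(no parameter moves more than half its magnitude per step), preceded by EM
warm-up iterations; proposals outside the parameter space are projected
(variances floored at 1e-10 x scale, covariances clipped into the PSD
cone). Standard errors come from the inverse AI matrix; correlation SEs by
the delta method. Convergence: |delta log L| < 1e-8 and relative component
change < 1e-6 (engine defaults; heavier composite fits override as noted).

Exactness is tested against dense GLS oracles: BLUP solutions, leverages
and PEV match closed-form generalized least squares to 1e-8 on random small
models, and REML variance components match an independent implementation
(statsmodels MixedLM) on identity-structure models.

## Evaluation machinery

* **Theoretical accuracy** r = sqrt(1 - PEV/sigma2_a). The source formula
  divides "the standard error for the EBV" by sigma2_a; only PEV (its
  square) is dimensionally consistent, so PEV is used.
* **Deregression** removes parent-average information before GWAS. The 2x2
  mixed-model system for the parent-average pseudo-animal and the
  individual is solved in closed form from the two reliabilities
  (r2_PA = (r2_s + r2_d)/4, missing parents contribute 0); the deregressed
  proof is the own-information right-hand side over the own information
  content. Founders (no parent average) reduce to dEBV = EBV/r2. Weights
  w = (1-h2)/((c + (1-r2)/r2) h2) with c = 0.5 by default (the fraction of
  genetic variance not captured by markers; unstated in the source).
  The GWAS uses unweighted dEBV; weights are emitted for completeness.
* **Cross-validation**: paternal families with >= 3 recorded half-sisters;
  per fold one (seeded, disjoint across folds) daughter per family is
  masked, both tracks are re-fit on the training records, and predicted
  variability EBV of masked sows are correlated with their realized
  log within-sow variance of TNB. A paired one-sided t-test across folds
  (df = k-1) asks whether the DHGLM is more precise; a paired test was
  chosen because fold-level correlations share the family structure.

## GWAS

Deregressed EBV are regressed on each SNP dosage with a VanRaden method-1
GRM absorbing polygenic covariance. Null components are estimated once by
REML on the GRM eigendecomposition; each SNP is then a generalized
least-squares fit with the variance ratio fixed (the standard fast
approximation; per-SNP REML changes nothing detectable at these effect
sizes). Thresholds: significant p < 1e-6, suggestive p < 1e-4. A vQTL
region is a significant SNP plus same-chromosome suggestive SNPs with
r^2 >= 0.2 to it (the source requires LD but prints no cutoff; 0.2 is the
conventional weak-LD floor and is configurable); overlapping regions merge,
the index SNP is the member with minimum p. Genotype QC: autosomal mapped
SNPs, call rate >= 0.95, MAF >= 0.01, Hardy-Weinberg Pearson chi-square
<= 600, then animals with > 5% missing genotypes. SNP variance explained:
sigma2_snp = 2 p q beta^2, reported against both the GWAS additive variance
and the phenotypic variance. Inflation factor: median observed 1-df
chi-square over 0.4549.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes and
nothing more. Mating is factorial: each generation has `n_sires` boars and
`n_dams_per_sire` shared dams (a sow farrows to several boars across
parities, as in commercial herds), one offspring per cross; non-promoted
offspring are recorded sows. Breeding-value pairs propagate as parent
average plus Mendelian sampling with covariance `D_i * G0`, `D_i` the
inbreeding-adjusted within-family variance from the same Meuwissen-Luo
computation used at fitting time, so simulated values are exactly
consistent with the A-matrix. Genotypes are gene-dropped with Bernoulli
recombination between adjacent loci (no interference; only the LD decay
shape matters downstream). Herd-year-season effects are drawn once per
level (SD 0.7); parity effects default to a concave curve peaking at parity
4-5. Defaults are the study conditions: mean TNB 13.76, sigma2_a = 1.33,
sigma2_pe = 0.86, exp(eta) = 7.67, sigma2_av = 0.037, sigma2_pev = 0.15,
r(a,av) = 0.43, r(pe,pev) = -0.87, 2-10 litters per sow, MAF uniform on
[0.05, 0.5]. The phenotype is continuous by default (the fitted models are
Gaussian); integer rounding/clamping is available to mimic the count nature
of real TNB, and whether that discreteness matters to the DHGLM is left to
the user to probe — the generator deliberately exposes both modes.

What the generator does **not** emulate: selection over generations,
genotyping error, realistic genome maps, non-Gaussian litter-size tails,
herd-by-time confounding. Passing recovery tests therefore show the
estimators are correct under their own assumptions, not that real pig data
satisfy those assumptions.

## Problem sizes and test design

The source population (~121,000 sows, 607,000 records, 526,000 SNPs) is
scaled to desk size for the test suite, as the package's own choice of
verification scale: REML recovery uses ~1,500 sows x 3-8 litters; DHGLM
recovery ~780 sows; the null and grid checks 400-600 sows; cross-validation
750 sows in 150 paternal families of five (4-8 litters per sow, so the
variance-part genetics stays estimable from a few hundred sows — with
mostly 2-3-litter sows neither track can estimate it at this n and the
method comparison degenerates to noise); GWAS power 3,000 animals with a
2,000-SNP GRM (dense enough that no single marker dominates its own
polygenic direction) and a planted variance-QTL effect of 0.1 on the dEBV
scale at MAF 0.3; and the permutation-null inflation check 1,500 animals x
2,000 SNPs. Recovery assertions are made against the simulated truth within
two reported standard errors; at these sizes SEs are several-fold wider
than in the source study, which is what scaled-down replication can
honestly support.

## Known limitations

* Variance-part SEs (hence correlation SEs) come from the AI matrix of the
  final joint fit and inherit the usual REML small-sample optimism.
* The DHGLM residual-variance prediction `exp(psi_hat)` is a point
  prediction; no uncertainty is propagated into it.
* The GWAS holds the null variance ratio fixed per SNP; exact per-SNP REML
  is available (`per_snp_reml`) but quadratic-time in panel size.
* No genomic-BLUP/single-step evaluation, no maternal or dominance effects,
  no imputation, phasing or annotation.
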