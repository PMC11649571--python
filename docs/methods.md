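# Methods

This note documents the statistical models implemented in `genarch`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## LD-score regression (`genarch.ldsc`)

**Model.** For a single trait, the expected association χ² of SNP j is
linear in its LD score ℓ_j:  E[χ²_j] = 1 + N·a + N·h²·ℓ_j/M, with M the
number of SNPs the heritability denominator refers to and a free intercept
absorbing confounding.  For two traits, E[z₁_j z₂_j] = √(N₁N₂)·ρ_g·ℓ_j/M + c,
where the intercept c absorbs phenotypic correlation among shared samples —
overlap therefore never biases the slope, which is the identifiability the
whole pipeline rests on.

**Weights.** Both regressions are two-step weighted least squares.  Step 1
uses 1/(ℓ·het₁·het₂) with het_t = 1 + N_t h²₀ ℓ/M seeded by the crude
closed-form h²₀ = (mean χ² − 1)·M/(N·mean ℓ); step 2 refreshes weights with
the full variance form Var(z₁z₂) = het₁·het₂ + E[z₁z₂]², taking the mean
line from the step-1 fit.  The univariate regression is implemented as the
cross-regression of a trait with itself, so a self-pair reproduces the
univariate fit to the last bit and the self-correlation is exactly 1.

**Uncertainty.** Standard errors come from a delete-a-block jackknife over
200 contiguous equal-SNP blocks (configurable).  One partition is shared by
all univariate and cross-trait regressions of a multi-trait run, so the
delete-block replicates of all k(k+1)/2 elements of S are computed on
identical SNP subsets and their empirical covariance is a coherent estimate
of V.  The genetic-correlation SE uses the JK1 form — deviations of the
delete-block *ratios* around the full-sample ratio — which coincides with
the mean-centred form for linear statistics and is the appropriately
conservative choice for the nonlinear ratio.  Measured against replicate
SDs under the generator, the h² SE is calibrated to within a few percent and
the 2-SE interval for r_g attains ~95–97% coverage across effect sizes.

**Liability conversion.** Observed-scale (co)heritabilities of case-control
traits are multiplied by K²(1−K)²/(P(1−P)·φ(t)²) per trait (square-root
factor per trait on off-diagonals), t = Φ⁻¹(1−K); correlations are invariant.
At K = P = 0.5 the factor is exactly π/2, a closed-form test anchor.

**Reporting conventions.** r_g is clamped to [−1, 1] for reporting (the
unclamped value is used internally); traits with non-positive estimated h²
yield undefined (NaN) correlations rather than imaginary ones.  If V (or a
correlation matrix headed into factor analysis) is not PSD, eigenvalues are
clipped at 1e−6 (`smooth_psd`).

## Genomic SEM (`genarch.sem`)

**Estimation.** Confirmatory models minimise the DWLS discrepancy
(s − σ(θ))ᵀ diag(V)⁻¹ (s − σ(θ)) with σ = vech(ΛΨΛᵀ + Θ).  Factors are
scaled by fixing their variances to 1; loadings, factor correlations and
residual variances are free unless the model text fixes them.  Residuals are
*unbounded* by default so Heywood cases surface as recorded warnings rather
than being silently truncated; `bound_residuals=True` enforces Θ ≥ 0 when an
interpretable solution is required.  On noisy covariance matrices the
unconstrained DWLS optimum genuinely can be a Heywood solution (we verified
its objective beats the bounded optimum on such panels) — that is a property
of the data, not an optimizer failure, and it is flagged, never hidden.

**Optimisation.** L-BFGS-B with the analytic Jacobian of σ(θ); five starts
(first unjittered, then 15% multiplicative jitter, fixed seed), objective
tolerance 1e−10.  Starting values and sanity bounds are keyed to the
observed variances (loadings within ±3 observed SDs, residuals within ±5
observed variances, factor correlations within ±0.999): on the h²-scale
covariance matrices this pipeline works on, scale-free starts put the
optimizer an order of magnitude off and occasionally strand it — the bounds
exclude the degenerate huge-loading/negative-residual region without
constraining any plausible solution.  Degenerate observed variances (null
panels can produce small negative diagonal estimates) are floored at the
panel-average magnitude for starts/bounds/standardisation only.

**Fit statistics.** Model χ² is the full-V quadratic form e'V⁺e of the vech
residual (V pseudo-inverted after PSD smoothing); df = k(k+1)/2 − q;
AIC = χ² + 2q (ΔAIC ordering, not the absolute value, is the tested
contract); CFI = 1 − max(χ²_m − df_m, 0)/max(χ²_b − df_b, χ²_m − df_m, 0)
against a free-variances/zero-covariances baseline; SRMR is the RMS of the
standardized residual matrix (lower triangle plus diagonal, standardized by
the observed SDs).  Parameter SEs are the sandwich
(JᵀWJ)⁻¹JᵀW V W J(JᵀWJ)⁻¹ with W = diag(V)⁻¹.  End-to-end (generator →
LDSC → CFA), ≥95% of true loadings fall within 2 sandwich SEs.

**EFA.** Exploratory analysis runs on the correlation matrix (CFA on the
covariance matrix with a standardized solution — the method's usual
division of labour): maximum-likelihood extraction via statsmodels with a
principal-axis fallback when ML fails, followed by an in-package promax
rotation (varimax, then oblique Procrustes to the 4th-power target;
Hendrickson–White).  ML is the default because at reduced study scale it
recovers the known cluster structure distinctly more reliably than principal
axis.  The rotation is in-package because the library routine returns NaN on
exact-zero loadings — precisely the block-structure oracle case the tests
use.  Variance explained is the mean communality under the oblique solution;
cluster assignment is by max-|pattern-loading|.

## Latent-factor GWAS (`genarch.factor_gwas`)

Each SNP enters the fitted model as an exogenous predictor of one factor.
On the standardized scale the SNP has variance v = 2p(1−p) and observed
SNP–trait covariances g_t = z_t·√(v/n_t), whose sampling covariance is
I_tu·√(v/n_t)·√(v/n_u) with I the LDSC intercept matrix (unit diagonal;
off-diagonals clamped to ±0.95 and PSD-projected, since estimated intercepts
can stray off the correlation manifold on small panels).  With base
parameters held at their no-SNP estimates, the single free path b has the
closed-form GLS solution b = (xᵀΣ⁻¹g)/(xᵀΣ⁻¹x), x_t = v·λ_tF, with
se = (xᵀΣ⁻¹x)^{−1/2} — the default, fully vectorised over SNPs.  A joint
re-fit of all parameters through the DWLS machinery is available behind
`refit=True`; the two agree closely on well-identified models and the
closed form is orders of magnitude faster.  Holding base parameters fixed is
the pragmatic default for a scan over millions of SNPs; the robustness cost
is negligible when no single SNP moves the genome-wide covariance, which is
exactly the regime the scan operates in.

Identity contract: a single-indicator factor with zero residual returns the
trait's own z-scores to machine precision.  Calibration: on a null panel the
per-SNP test is uniform (type-I 0.05 ± 0.01 at 20,000 SNPs).  The implied
effective N written into the factor's sumstats is mean(1/(se_b²·v)), which
makes the output directly consumable by LDSC.  SNPs for which the extended
model cannot be evaluated (monomorphic, failures under `refit`) are skipped
and counted, never silently dropped.

## Polar pleiotropy (`genarch.polar`)

Whitening uses u = L⁻¹z with L the Cholesky factor of [[1, c], [c, 1]]; c is
the cross-trait LDSC intercept when available, else the empirical
correlation of SNPs with both |z| < 1.96.  Then r = √(u₁²+u₂²) and
Θ = arctan(|u₂|/|u₁|), folded to [0, π/2]; (0,0) records carry an undefined
angle and are flagged.  p_r = exp(−r²/2) exactly.  p_Θ is simulated under
the single-trait-effect null conditional on the observed r: signal r on one
axis plus standard bivariate noise (the two axes are equivalent under the
fold), antithetic draws, fixed seed; the p-value is the probability of an
angle at least as close to π/4 as observed.  The null is simulated once per
radius on a grid of up to 256 quantile-spaced radii (100,000 draws each by
default) and each SNP interpolates between bracketing radii — an analytic
fast path, if added later, must agree with this simulation within
Monte-Carlo error; the simulation is the reference.

FDR is Benjamini–Hochberg per family (r and Θ separately, via statsmodels);
selection requires q < 0.05 on both.  Clumping is greedy by ascending p_r
(the ranking p-value choice is a package decision): unassigned SNPs below
5×10⁻⁸ found clumps; members join within 500 kb at r² ≥ 0.4 below 0.05;
overlapping clump intervals merge into loci; anything touching
chr6:25–34 Mb (GRCh37, configurable) collapses into a single MHC locus.
Missing LD pairs count as r² = 0 with a logged tally.  λ is
median(χ²)/0.45494; λ₁₀₀₀ is reported in the case-control form
1 + (λ−1)(1/cases + 1/controls)·500 and in an equal-split form, since which
scaling a two-trait pleiotropy context should use is a judgment call.

## Synthetic data (`genarch.simulate`)

The generator works at the summary-statistic level: for SNP j the trait
z-vector is MVN with covariance Σ_j = C + (ℓ_j/M)·D R D, where R is the
correlation matrix implied by the configured factor model
(R = ΛΨΛᵀ + diag(residuals)), D = diag(√(N h²)), and C is the intercept
matrix (unit diagonal; off-diagonals = overlap fraction × phenotypic
correlation).  This is exactly the sampling model the LDSC regressions
assume, so truth is analytic at every stage: mean χ² = 1 + N h² mean(ℓ)/M,
cross-product slopes equal √(N₁N₂)ρ_g/M, intercepts equal C.  LD scores are
1 + Gamma(shape 4, mean 100 by default) — positive and right-skewed — with a
constant-ℓ option for closed-form checks.  Spiked pleiotropic SNPs add the
mean shift L_C·(r cos α, r sin α) so their whitened effects land on the
configured sharedness angle α in expectation.

What this does **not** emulate: real LD structure (SNPs are independent
draws; ℓ_j is a label, not a consequence of neighbouring genotypes),
population stratification, allele-frequency-dependent architectures,
imputation error correlated with INFO, and case-control ascertainment beyond
the effective-N approximation.  Passing tests therefore demonstrate
correctness of the estimators *under the model they assume*, not robustness
to model violations in real data.

**The packaged ten-trait scenario** (`study_scale_scenario`) encodes a
five-factor truth over OCD, AN, TS, BIP, SCZ, ANX, MDD, ADHD, AUT, DYX:
compulsive, psychotic, internalising, neurodevelopmental, and
attention/learning factors.  Anchored quantities: ADHD loads 0.43 on the
neurodevelopmental and 0.75 on the attention/learning factor; residual
variances 0.78 (DYX), 0.56 (AUT), ≈0.10 (ADHD); the attention/learning
factor correlates 0.40/0.25/0.17/−0.16 with the
internalising/neurodevelopmental/psychotic/compulsive factors.  The
remaining loadings were chosen once so the implied pairwise correlations hit
the well-replicated anchors (ANX–MDD 0.86, BIP–SCZ 0.69, AN–OCD ≈ 0.42,
ADHD–DYX 0.40, AUT–DYX ≈ 0.08 and non-significant), and the remaining factor
correlations are moderate values typical of published multi-disorder models;
the implied matrix is PSD and its noiseless EFA reproduces the four-cluster
structure {OCD,AN,TS} {BIP,SCZ} {ANX,MDD} {ADHD,AUT,DYX}.  Default desk
scale is 1/20 of the study: effective sample sizes from the ten
case-control designs divided by 20, and 41,518 SNPs (the same fraction of
the 830,359 regression SNPs).  Per-trait observed-scale h² values are
plausible choices (0.08–0.30) sized so every heritability z-score clears the
>4 screen at this scale.  Desk-scale runs of the whole pipeline
(~40k SNPs × 10 traits → LDSC → EFA/CFA) take a few seconds each; the test
suite's replicate counts (20–100 per property) keep the full run near three
minutes on one CPU.

## Degenerate inputs and tie-breaks

- Duplicate SNP ids: first record kept, rest logged.
- Strand-ambiguous A/T and C/G records are dropped during harmonisation
  (sign safety outweighs the SNP loss).
- Clumping ties in p are broken by SNP id for determinism.
- BH q-values pass NaN p-values through as NaN; selection treats NaN as
  not-significant.
- A trait regressed on itself yields SE 0; the scan reports p = 0 for
  |r_g| > 0 rather than NaN.

## Known limitations

- No partitioned/annotation-stratified heritability, no LD-score
  computation from genotype panels, no liftover, no more-than-two-trait
  polar generalisation, no gene mapping or enrichment downstream of the
  locus table — all out of scope by design.
- The Θ null simulation is the reference implementation; it costs ~1 s per
  10⁵ SNPs at default draw counts but is Monte-Carlo, so q_Θ values carry
  simulation noise of order 1/√draws.
- Absolute AIC values depend on the χ² definition (full-V quadratic form);
  only model *ordering* is contractual.
- The factor-GWAS effective N is an approximation adequate for feeding LDSC;
  it is not a per-SNP sample size.
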