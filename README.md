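# genarch

Multi-trait genetic-architecture analysis from GWAS summary statistics:
LD-score regression, genomic structural equation modelling, latent-factor
GWAS, and polar-coordinate detection of pleiotropic variants shared by two
traits.

## Who this is for

Statistical geneticists who have per-trait GWAS summary statistics (never
genotypes) for a panel of related phenotypes — the motivating use case is a
panel of ten neurodevelopmental and psychiatric conditions including dyslexia
and ADHD — and want to:

1. estimate SNP heritabilities and the genetic covariance matrix **S** across
   traits, with a block-jackknife sampling covariance **V** (LD-score
   regression);
2. model the latent factor structure of **S** (exploratory factor analysis
   with promax rotation; confirmatory models fitted by diagonally weighted
   least squares, compared by AIC/CFI/SRMR);
3. run a GWAS of a latent factor by extending the fitted model with one SNP
   at a time; and
4. find SNPs shared by two traits via a polar transform of whitened z-scores,
   with dual FDR control and LD clumping into genomic risk loci.

A synthetic-data module generates summary statistics under a known factor
model so that every stage has a recoverable analytic truth.

## The model

For SNP j with LD score ℓ_j, LD-score regression uses

    E[χ²_j]      = 1 + N·a + N·h²·ℓ_j/M                 (one trait)
    E[z_1j z_2j] = √(N₁N₂)·ρ_g·ℓ_j/M + c                (two traits)

where M is the regression SNP count; the free intercepts absorb confounding
(a) and sample overlap (c).  Standard errors and **V** come from a
delete-a-block jackknife over a partition shared by every regression.

Confirmatory models minimise the diagonally weighted least-squares
discrepancy (s − σ(θ))ᵀ D⁻¹ (s − σ(θ)) with s = vech(S), σ = vech(ΛΨΛᵀ + Θ)
and D = diag(V); parameter SEs use the full-**V** sandwich, factor variances
are fixed to 1, and fit is summarised by χ² (full-**V** quadratic form),
AIC = χ² + 2q, CFI against the free-variances independence baseline, and
SRMR.

For the pleiotropy scan, a SNP's z-score pair is whitened by the inverse
Cholesky factor of [[1, c], [c, 1]] (c = cross-trait LDSC intercept), then

    r = √(u₁² + u₂²),    Θ = arctan(|u₂|/|u₁|) ∈ [0, π/2],

with Θ = π/4 meaning equal shared effects.  p_r = exp(−r²/2) (χ²₂ survival);
p_Θ is Monte-Carlo under a single-trait-effect null conditional on r.  SNPs
with Benjamini–Hochberg q < 0.05 on *both* statistics are clumped
(r² ≥ 0.4 within 500 kb of a lead with p < 5×10⁻⁸; members p < 0.05; the MHC
region counts as one locus).

## Worked example

```python
import numpy as np
from genarch import simulate as sim, ldsc, sem

# ten-trait panel at 1/20 of the motivating study's sample sizes
cfg = sim.study_scale_scenario(seed=1)
tables, ldscores, truth = sim.simulate_panel(cfg)

cov = ldsc.multivariate_ldsc(tables, ldscores)      # S, V, intercepts
R = cov.rg()
i, j = cov.traits.index("ADHD"), cov.traits.index("DYX")
print(f"rg(ADHD, DYX) = {R[i, j]:.3f} +- {cov.rg_se[i, j]:.3f}")

efa = sem.fit_efa(R, 4, trait_names=cov.traits)
five = sem.parse_model("""
F1 =~ OCD + AN + TS
F2 =~ BIP + SCZ
F3 =~ ANX + MDD
F4 =~ ADHD + AUT
F5 =~ ADHD + DYX
""", traits=cov.traits)
fit = sem.fit_cfa(cov, five)
print(f"AIC = {fit.aic:.1f}, CFI = {fit.cfi:.3f}, SRMR = {fit.srmr:.3f}")
```

prints (seed 1):

```
rg(ADHD, DYX) = 0.396 +- 0.015
AIC = 111.8, CFI = 0.998, SRMR = 0.021
```

The estimated ADHD–dyslexia genetic correlation sits within two standard
errors of the generating truth (0.40), and the five-factor model — whose
fifth factor carries the shared attention/learning liability of ADHD and
dyslexia — fits the estimated covariance nearly perfectly.

The same workflow runs from the shell via the `genarch` command
(`simulate`, `munge`, `ldsc`, `run`, `report`, ...); `genarch run config.yaml`
executes munge → LDSC → EFA/CFA → optional factor GWAS → optional pleiotropy
scan, checkpointing every artifact with checksums into a run directory.

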