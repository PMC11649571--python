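"""Per-SNP association with a latent genomic factor.

The fitted structural model is extended SNP by SNP with the variant as an
exogenous predictor of one factor (F = b*SNP + disturbance).  On the
standardized scale the SNP contributes variance v = 2*freq*(1-freq) and a
covariance with each indicator trait t of

    g_t = beta_t * v,     beta_t = z_t / sqrt(n_t * v),

with sampling covariance  Cov(g_t, g_u) = I_tu * sqrt(v/n_t) * sqrt(v/n_u)
where I is the LDSC intercept matrix (diagonal ~1; off-diagonals absorb
sample overlap).  The model-implied counterpart is b * v * lambda_tF, so with
the base-model parameters held at their no-SNP estimates the single free path
b has the closed-form GLS solution

    b = (x' Sigma^-1 g) / (x' Sigma^-1 x),   x_t = v * lambda_tF,

with se(b) = (x' Sigma^-1 x)^{-1/2}.  A full re-fit of all base parameters
together with b through the DWLS machinery is available behind
``refit=True``; it is orders of magnitude slower and changes per-SNP z only
marginally on well-identified models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import GeneticCovariance, vech_index
from .sem import SemFit, SemModel, _Parameterisation, fit_cfa
from .sumstats import CANONICAL_COLUMNS, SumstatsTable

logger = logging.getLogger(__name__)

__all__ = ["AugmentedCovariance", "FactorGwasRecord", "expand_covariance",
           "snp_factor_assoc", "run_factor_gwas"]


@dataclass
class AugmentedCovariance:
    """(k+1)x(k+1) covariance with the SNP appended as the last variable."""

    base: GeneticCovariance
    snp_id: str
    snp_variance: float           # 2*freq*(1-freq)
    snp_trait_cov: np.ndarray     # (k,) g_t
    snp_sampling_cov: np.ndarray  # (k, k) sampling covariance of g

    @property
    def S(self) -> np.ndarray:
        k = self.base.k
        S = np.zeros((k + 1, k + 1))
        S[:k, :k] = self.base.S
        S[k, :k] = S[:k, k] = self.snp_trait_cov
        S[k, k] = self.snp_variance
        return S


def _noise_correlation(cov: GeneticCovariance) -> np.ndarray:
    """Per-SNP noise correlation across traits: the LDSC intercept matrix with
    unit diagonal, off-diagonals clamped to (-0.95, 0.95) and the result
    projected to the nearest positive-definite matrix.  Estimation noise in
    the intercepts must not leave the correlation manifold, or per-SNP
    sampling covariances stop being valid."""
    from .ldsc import smooth_psd
    icept = np.clip(cov.intercepts.copy(), -0.95, 0.95)
    np.fill_diagonal(icept, 1.0)
    icept = smooth_psd(icept, eps=1e-3)
    d = np.sqrt(np.diag(icept))
    return icept / np.outer(d, d)


@dataclass
class FactorGwasRecord:
    snp_id: str
    factor: str
    beta: float
    se: float
    z: float
    p: float


def expand_covariance(cov: GeneticCovariance, z: np.ndarray, n: np.ndarray,
                      freq: float, snp_id: str = "SNP") -> AugmentedCovariance:
    """Augment the genetic covariance with one SNP's standardized effects.

    Raises ValueError for a monomorphic SNP (variance zero); callers stream
    over SNPs and skip-and-count such records.
    """
    v = 2.0 * freq * (1.0 - freq)
    if not (v > 0):
        raise ValueError(f"monomorphic SNP {snp_id} (freq={freq})")
    z = np.asarray(z, float)
    n = np.asarray(n, float)
    if z.shape != (cov.k,) or n.shape != (cov.k,):
        raise ValueError("need one z and one n per trait")
    se_g = np.sqrt(v / n)                    # se of each SNP-trait covariance
    g = z * se_g                             # beta_t * v
    sigma = _noise_correlation(cov) * np.outer(se_g, se_g)
    return AugmentedCovariance(base=cov, snp_id=snp_id, snp_variance=v,
                               snp_trait_cov=g, snp_sampling_cov=sigma)


def _factor_loadings_on(fit: SemFit, factor: str) -> np.ndarray:
    """Unstandardized loadings of every trait on ``factor`` at the fitted
    parameters (traits not loading on it contribute 0)."""
    par = _Parameterisation(fit.model)
    lam, _, _ = par.unpack(fit.theta)
    f = fit.model.factors.index(factor)
    return lam[:, f]


def snp_factor_assoc(aug: AugmentedCovariance, fit: SemFit, factor: str,
                     refit: bool = False) -> FactorGwasRecord:
    """Estimate the SNP -> factor path on one augmented covariance.

    Default: base parameters fixed at their no-SNP estimates, single free
    path solved by GLS (closed form).  ``refit=True`` re-estimates every base
    parameter jointly with the path through the DWLS optimizer.
    """
    if factor not in fit.model.factors:
        raise ValueError(f"unknown factor {factor}")
    if refit:
        return _snp_factor_assoc_refit(aug, fit, factor)
    lam_f = _factor_loadings_on(fit, factor)
    x = aug.snp_variance * lam_f
    sigma_inv = np.linalg.pinv(aug.snp_sampling_cov)
    xtsi = x @ sigma_inv
    denom = float(xtsi @ x)
    if denom <= 0:
        raise ValueError("factor has no loaded indicators with finite precision")
    b = float(xtsi @ aug.snp_trait_cov) / denom
    se = 1.0 / np.sqrt(denom)
    zval = b / se
    return FactorGwasRecord(snp_id=aug.snp_id, factor=factor, beta=b, se=se,
                            z=zval, p=float(2 * stats.norm.sf(abs(zval))))


def _snp_factor_assoc_refit(aug: AugmentedCovariance, fit: SemFit,
                            factor: str) -> FactorGwasRecord:
    """Joint re-fit: appends the SNP as a fixed-variance single-indicator
    exogenous variable and frees the regression path within the DWLS model."""
    base = fit.model
    k = aug.base.k
    snp_name = "_SNP_"
    traits = list(base.traits) + [snp_name]
    factors = list(base.factors) + ["F_SNP"]
    loadings = dict(base.loadings)
    loadings[(snp_name, "F_SNP")] = np.sqrt(aug.snp_variance)
    # regression of `factor` on the SNP enters Psi as a free covariance; all
    # other SNP-factor covariances are fixed at zero
    factor_cov = dict(base.factor_cov)
    for f in base.factors:
        factor_cov[(f, "F_SNP")] = None if f == factor else 0.0
    residuals = dict(base.residuals)
    residuals[snp_name] = 0.0
    model = SemModel(factors=factors, traits=traits, loadings=loadings,
                     factor_cov=factor_cov, residuals=residuals,
                     bound_residuals=base.bound_residuals)

    # augmented covariance object with V extended by the SNP sampling terms
    S = aug.S
    old_idx = vech_index(k)
    new_idx = vech_index(k + 1)
    p_new = len(new_idx)
    V = np.zeros((p_new, p_new))
    pos_old = {pair: p for p, pair in enumerate(old_idx)}
    for a, (i, j) in enumerate(new_idx):
        for b_, (l, m) in enumerate(new_idx):
            if (i, j) in pos_old and (l, m) in pos_old:
                V[a, b_] = aug.base.V[pos_old[(i, j)], pos_old[(l, m)]]
            elif i == k and j < k and l == k and m < k:
                V[a, b_] = aug.snp_sampling_cov[j, m]
    var_pos = new_idx.index((k, k))
    V[var_pos, var_pos] = 1e-10  # SNP variance treated as known
    cov_aug = GeneticCovariance(traits=traits, S=S, V=V,
                                intercepts=np.eye(k + 1),
                                intercept_se=np.zeros((k + 1, k + 1)))
    new_fit = fit_cfa(cov_aug, model, n_starts=2, seed=7)
    tab = new_fit.parameter_table()
    row = tab[tab["parameter"] == f"{factor} ~~ F_SNP"]
    # psi entry is cov(factor, SNP-factor); path b = psi / sqrt(v) on the raw
    # SNP scale: cov(SNP, F) = psi * sqrt(v) = b * v
    psi_est = float(row["estimate"].iloc[0])
    psi_se = float(row["se"].iloc[0])
    b = psi_est / np.sqrt(aug.snp_variance)
    se = psi_se / np.sqrt(aug.snp_variance)
    zval = b / se if se > 0 else np.nan
    return FactorGwasRecord(snp_id=aug.snp_id, factor=factor, beta=b, se=se,
                            z=zval, p=float(2 * stats.norm.sf(abs(zval))))


def run_factor_gwas(tables: list[SumstatsTable], cov: GeneticCovariance,
                    fit: SemFit, factor: str,
                    refit: bool = False) -> tuple[SumstatsTable, dict]:
    """Latent-factor GWAS: one association record per shared SNP.

    ``tables`` must be intersected/harmonized (identical SNP order); ``cov``
    and ``fit`` are the no-SNP LDSC covariance and base model fit.  Returns a
    canonical sumstats table for the factor (Z, implied effective N) plus a
    log dict with skip tallies.  Deterministic: rerunning on the same inputs
    is bit-identical.

    The implied factor effective N is mean(1 / (se_b^2 * v)) over emitted
    SNPs, which makes the output directly consumable by LDSC.
    """
    ids = tables[0].df["SNP"].to_numpy()
    for t in tables[1:]:
        if not np.array_equal(t.df["SNP"].to_numpy(), ids):
            raise ValueError("tables must share an identical SNP order")
    z_mat = np.column_stack([t.df["Z"].to_numpy(float) for t in tables])
    n_mat = np.column_stack([t.df["N"].to_numpy(float) for t in tables])
    freq = tables[0].df["FREQ"].to_numpy(float)
    meta = tables[0].df[["SNP", "CHR", "BP", "A1", "A2", "FREQ"]]

    log = {"monomorphic": 0, "failed": 0}
    if not refit:
        # fully vectorized closed form
        v = 2.0 * freq * (1.0 - freq)
        ok = v > 0
        log["monomorphic"] = int((~ok).sum())
        lam_f = _factor_loadings_on(fit, factor)
        icept = _noise_correlation(cov)
        se_g = np.sqrt(v[ok, None] / n_mat[ok])           # (m, k)
        g = z_mat[ok] * se_g
        x = v[ok, None] * lam_f[None, :]
        # Sigma_j = icept * outer(se_g_j); solve per SNP via the scaled system:
        # Sigma^-1 = D^-1 icept^-1 D^-1 with D = diag(se_g_j)
        icept_inv = np.linalg.pinv(icept)
        x_scaled = x / se_g                               # D^-1 x
        g_scaled = g / se_g                               # D^-1 g  (= z)
        xtsi = x_scaled @ icept_inv                       # (m, k)
        denom = np.einsum("mk,mk->m", xtsi, x_scaled)
        numer = np.einsum("mk,mk->m", xtsi, g_scaled)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = numer / denom
            se = 1.0 / np.sqrt(denom)
        zval = beta / se
        records = pd.DataFrame({
            "SNP": meta.loc[ok, "SNP"].to_numpy(),
            "CHR": meta.loc[ok, "CHR"].to_numpy(),
            "BP": meta.loc[ok, "BP"].to_numpy(),
            "A1": meta.loc[ok, "A1"].to_numpy(),
            "A2": meta.loc[ok, "A2"].to_numpy(),
            "Z": zval, "BETA_STD": beta, "SE": se,
            "FREQ": freq[ok],
        })
        n_eff = 1.0 / (se ** 2 * v[ok])
    else:
        rows, n_eff_list = [], []
        for j in range(len(ids)):
            vj = 2.0 * freq[j] * (1.0 - freq[j])
            if not vj > 0:
                log["monomorphic"] += 1
                continue
            try:
                aug = expand_covariance(cov, z_mat[j], n_mat[j], freq[j], ids[j])
                rec = snp_factor_assoc(aug, fit, factor, refit=True)
            except Exception as exc:  # skip-and-count, never abort the scan
                log["failed"] += 1
                logger.debug("SNP %s failed: %s", ids[j], exc)
                continue
            rows.append((ids[j], meta["CHR"].iat[j], meta["BP"].iat[j],
                         meta["A1"].iat[j], meta["A2"].iat[j],
                         rec.z, rec.beta, rec.se, freq[j]))
            n_eff_list.append(1.0 / (rec.se ** 2 * vj))
        records = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2",
                                              "Z", "BETA_STD", "SE", "FREQ"])
        n_eff = np.asarray(n_eff_list)

    implied_n = float(np.nanmean(n_eff)) if len(n_eff) else np.nan
    records["N"] = implied_n
    records["INFO"] = np.nan
    out = records[CANONICAL_COLUMNS + ["BETA_STD", "SE"]]
    logger.info("factor GWAS of %s: %d records, %d monomorphic, %d failed",
                factor, len(out), log["monomorphic"], log["failed"])
    table = SumstatsTable(trait=factor, df=out.reset_index(drop=True), log=log)
    return table, log
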