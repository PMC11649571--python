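"""LD-score regression: heritabilities, intercepts, the genetic covariance
matrix S and its block-jackknife sampling covariance V.

The univariate model regresses per-SNP chi-square on the LD score,

    E[chi2_j] = 1 + N*a + N * h2 * l_j / M,

with a free intercept (1 + N*a); the slope times M/N-bar is the SNP
heritability.  The cross-trait model regresses the z-score product,

    E[z1_j z2_j] = sqrt(N1 N2) * rho_g * l_j / M + c,

where the free intercept c absorbs sample overlap.  Standard errors come from
a delete-a-block jackknife over contiguous SNP blocks; one shared block
partition is used for every regression of a multi-trait run so that the
sampling covariance V of vech(S) is coherent across elements.

Weights follow the usual two-step scheme: a first unweighted-in-h2 pass
estimates the slope, then heteroskedasticity + over-counting weights
1 / (l_j * (1 + N h2 l_j / M)^2) are formed and held fixed for the final fit
and for the jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDScoreTable, SumstatsTable, align_ldscores, effective_n

__all__ = [
    "HeritabilityEstimate", "GeneticCovariance", "LiabilityParams",
    "univariate_ldsc", "multivariate_ldsc", "to_liability", "rg_scan",
    "effective_n", "neff_rg_regression", "vech_index", "smooth_psd",
]

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.45494...


# ---------------------------------------------------------------------------
# results containers

@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chisq: float
    ratio: float | None  # (intercept-1)/(mean chi2 - 1); None if mean chi2 <= 1

    @property
    def z_h2(self) -> float:
        return self.h2 / self.h2_se


@dataclass
class LiabilityParams:
    """Sample case proportion P and population prevalence K of one trait."""
    P: float
    K: float

    def __post_init__(self) -> None:
        if not (0 < self.P < 1 and 0 < self.K < 1):
            raise ValueError("P and K must lie strictly inside (0, 1)")

    @property
    def factor(self) -> float:
        """Observed-to-liability conversion factor
        K^2 (1-K)^2 / (P (1-P) phi(t)^2), t = Phi^-1(1-K)."""
        t = stats.norm.ppf(1 - self.K)
        phi = stats.norm.pdf(t)
        return self.K ** 2 * (1 - self.K) ** 2 / (self.P * (1 - self.P) * phi ** 2)


def vech_index(k: int) -> list[tuple[int, int]]:
    """Row-wise lower-triangle (i >= j) index order used for vech(S) and V."""
    return [(i, j) for i in range(k) for j in range(i + 1)]


@dataclass
class GeneticCovariance:
    """Genetic covariance matrix S across traits with jackknife sampling
    covariance V of vech(S), LDSC intercepts, and per-trait diagnostics."""

    traits: list[str]
    S: np.ndarray                    # (k, k) symmetric
    V: np.ndarray                    # (k*(k+1)/2,)**2, vech order of vech_index
    intercepts: np.ndarray           # (k, k): diag univariate, off-diag cross-trait
    intercept_se: np.ndarray
    scale: str = "observed"          # "observed" or "liability"
    h2_estimates: list[HeritabilityEstimate] | None = None
    rg_se: np.ndarray | None = None  # jackknife SE of each r_g (k, k; diag 0)

    @property
    def k(self) -> int:
        return len(self.traits)

    def vech(self) -> np.ndarray:
        idx = vech_index(self.k)
        return np.array([self.S[i, j] for i, j in idx])

    def se_matrix(self) -> np.ndarray:
        """Jackknife SE of each element of S, unpacked from diag(V)."""
        se = np.zeros_like(self.S)
        for p, (i, j) in enumerate(vech_index(self.k)):
            se[i, j] = se[j, i] = np.sqrt(max(self.V[p, p], 0.0))
        return se

    def rg(self, clamp: bool = True) -> np.ndarray:
        """Genetic correlation matrix S_tu / sqrt(S_tt S_uu).

        Pairs involving a trait with non-positive heritability are undefined
        and returned as NaN.  Clamped to [-1, 1] for reporting by default."""
        d = np.diag(self.S).copy()
        bad = d <= 0
        d[bad] = np.nan
        denom = np.sqrt(np.outer(d, d))
        with np.errstate(invalid="ignore"):
            r = self.S / denom
        np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
        if clamp:
            r = np.clip(r, -1.0, 1.0)
        return r

    def subset(self, traits: list[str]) -> "GeneticCovariance":
        pos = [self.traits.index(t) for t in traits]
        k_new = len(pos)
        old_idx = {pair: p for p, pair in enumerate(vech_index(self.k))}
        rows = [old_idx[(max(pos[i], pos[j]), min(pos[i], pos[j]))]
                for i, j in vech_index(k_new)]
        sel = np.ix_(pos, pos)
        return GeneticCovariance(
            traits=list(traits), S=self.S[sel],
            V=self.V[np.ix_(rows, rows)],
            intercepts=self.intercepts[sel], intercept_se=self.intercept_se[sel],
            scale=self.scale,
            rg_se=None if self.rg_se is None else self.rg_se[sel])


# ---------------------------------------------------------------------------
# weighted regression with delete-a-block jackknife

def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n < n_blocks:
        raise ValueError(f"fewer SNPs ({n}) than jackknife blocks ({n_blocks})")
    return np.linspace(0, n, n_blocks + 1).astype(int)

def _wls_block_sums(ell: np.ndarray, y: np.ndarray, w: np.ndarray,
                    bounds: np.ndarray):
    """Per-block sufficient statistics of the weighted regression of y on
    [1, ell]: returns (n_blocks, 2, 2) X'WX and (n_blocks, 2) X'Wy arrays."""
    nb = len(bounds) - 1
    xtwx = np.empty((nb, 2, 2))
    xtwy = np.empty((nb, 2))
    for b in range(nb):
        s = slice(bounds[b], bounds[b + 1])
        wb, lb, yb = w[s], ell[s], y[s]
        sw = wb.sum()
        swl = (wb * lb).sum()
        xtwx[b] = [[sw, swl], [swl, (wb * lb * lb).sum()]]
        xtwy[b] = [(wb * yb).sum(), (wb * lb * yb).sum()]
    return xtwx, xtwy

def _solve(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.linalg.solve(a, c)

def _jackknife_fits(xtwx: np.ndarray, xtwy: np.ndarray):
    """Full-sample and delete-one-block (intercept, slope) estimates."""
    a_tot, c_tot = xtwx.sum(axis=0), xtwy.sum(axis=0)
    full = _solve(a_tot, c_tot)
    nb = xtwx.shape[0]
    deletes = np.empty((nb, 2))
    for b in range(nb):
        deletes[b] = _solve(a_tot - xtwx[b], c_tot - xtwy[b])
    return full, deletes

def _jackknife_se(deletes: np.ndarray) -> np.ndarray:
    nb = deletes.shape[0]
    mean = deletes.mean(axis=0)
    return np.sqrt((nb - 1) / nb * ((deletes - mean) ** 2).sum(axis=0))


def _two_step_fit(ell: np.ndarray, y: np.ndarray, het1: np.ndarray,
                  het2: np.ndarray, bounds: np.ndarray):
    """Weighted regression of y on [1, ell] with LDSC variance weights.

    Step 1 uses 1/(l * het1 * het2); step 2 adds the squared-mean term,
    Var(z1 z2) = het1*het2 + E[z1 z2]^2, with the mean line taken from the
    step-1 fit.  Returns full-sample and delete-one-block estimates."""
    lf = np.maximum(ell, 1.0)
    w = 1.0 / (lf * het1 * het2)
    xtwx, xtwy = _wls_block_sums(ell, y, w, bounds)
    (c1, s1), _ = _jackknife_fits(xtwx, xtwy)
    mean = c1 + s1 * lf
    w = 1.0 / (lf * (het1 * het2 + mean * mean))
    xtwx, xtwy = _wls_block_sums(ell, y, w, bounds)
    return _jackknife_fits(xtwx, xtwy)


def _uni_regression(z: np.ndarray, n: np.ndarray, ell: np.ndarray, m: float,
                    bounds: np.ndarray):
    """Two-step weighted chi2-on-ell regression; returns full fit and
    delete-block fits as (intercept, h2) plus the crude h2 used to seed the
    heteroskedasticity lines.

    The crude seed (not the refined fit) is what the cross-trait weights
    receive, so a trait regressed on itself runs the numerically identical
    pipeline and reproduces this regression exactly."""
    chi2 = z * z
    nbar = float(n.mean())
    h2_0 = max((chi2.mean() - 1.0) / (nbar * ell.mean() / m), 0.0)
    lf = np.maximum(ell, 1.0)
    het = 1.0 + h2_0 * nbar * lf / m
    full, deletes = _two_step_fit(ell, chi2, het, het, bounds)
    conv = np.array([1.0, m / nbar])
    return full * conv, deletes * conv, h2_0


def univariate_ldsc(table: SumstatsTable, ld: LDScoreTable,
                    n_blocks: int = 200) -> HeritabilityEstimate:
    """SNP heritability and confounding intercept of one trait.

    Returns the heritability on the observed scale with delete-a-block
    jackknife SEs over ``n_blocks`` contiguous SNP blocks.
    """
    (aligned,), ell = align_ldscores([table], ld)
    z = aligned.df["Z"].to_numpy(float)
    n = aligned.df["N"].to_numpy(float)
    bounds = _block_bounds(len(z), n_blocks)
    (a, h2), deletes, _ = _uni_regression(z, n, ell, ld.m, bounds)
    se = _jackknife_se(deletes)
    mean_chisq = float((z * z).mean())
    ratio = float((a - 1.0) / (mean_chisq - 1.0)) if mean_chisq > 1 else None
    return HeritabilityEstimate(trait=aligned.trait, h2=float(h2), h2_se=float(se[1]),
                                intercept=float(a), intercept_se=float(se[0]),
                                mean_chisq=mean_chisq, ratio=ratio)


def _cross_regression(z1, z2, n1, n2, ell, m, bounds, h2_1, h2_2):
    """Cross-trait z1*z2-on-ell regression; returns (intercept, rho_g) full and
    delete-block estimates, slope converted to genetic-covariance scale.

    Two-step weights follow Var(z1 z2) = het1 * het2 + E[z1 z2]^2 with
    het_t = 1 + N_t h2_t l/M seeded by the crude univariate h2; the
    squared-mean term uses the step-1 line.  A trait paired with itself runs
    the numerically identical pipeline as the univariate regression."""
    y = z1 * z2
    root_n = np.sqrt(n1.mean() * n2.mean())
    lf = np.maximum(ell, 1.0)
    het1 = 1.0 + np.maximum(h2_1, 0) * n1.mean() * lf / m
    het2 = 1.0 + np.maximum(h2_2, 0) * n2.mean() * lf / m
    full, deletes = _two_step_fit(ell, y, het1, het2, bounds)
    conv = np.array([1.0, m / root_n])
    return full * conv, deletes * conv


def multivariate_ldsc(tables: list[SumstatsTable], ld: LDScoreTable,
                      n_blocks: int = 200) -> GeneticCovariance:
    """Genetic covariance matrix S, intercept matrix and block-jackknife V.

    All tables must already be intersected to a common SNP set; a single
    block partition is shared by every univariate and cross-trait regression
    so the delete-block replicates of every element of S are computed on the
    same SNP subsets and V captures their sampling covariance coherently.
    """
    if len(tables) < 2:
        raise ValueError("need at least two traits")
    ids = tables[0].df["SNP"].to_numpy()
    for t in tables[1:]:
        if len(t.df) != len(ids) or not np.array_equal(t.df["SNP"].to_numpy(), ids):
            raise ValueError("tables must be intersected to a shared SNP set first "
                             "(see sumstats.intersect)")
    aligned, ell = align_ldscores(tables, ld)
    k = len(aligned)
    z = np.column_stack([t.df["Z"].to_numpy(float) for t in aligned])
    n = np.column_stack([t.df["N"].to_numpy(float) for t in aligned])
    bounds = _block_bounds(z.shape[0], n_blocks)
    nb = n_blocks

    idx = vech_index(k)
    p_star = len(idx)
    S = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    intercept_se = np.zeros((k, k))
    delete_vech = np.empty((nb, p_star))
    h2_full = np.zeros(k)
    h2_weight = np.zeros(k)
    h2_deletes = np.empty((nb, k))
    h2_list: list[HeritabilityEstimate] = []

    # univariate fits first (their h2 feeds the cross-trait weights)
    for t in range(k):
        (a, h2), deletes, h2_w = _uni_regression(z[:, t], n[:, t], ell, ld.m, bounds)
        se = _jackknife_se(deletes)
        mean_chisq = float((z[:, t] ** 2).mean())
        h2_list.append(HeritabilityEstimate(
            trait=aligned[t].trait, h2=float(h2), h2_se=float(se[1]),
            intercept=float(a), intercept_se=float(se[0]), mean_chisq=mean_chisq,
            ratio=float((a - 1) / (mean_chisq - 1)) if mean_chisq > 1 else None))
        S[t, t] = h2
        intercepts[t, t] = a
        intercept_se[t, t] = se[0]
        h2_full[t] = h2
        h2_weight[t] = h2_w
        h2_deletes[:, t] = deletes[:, 1]

    rho_deletes: dict[tuple[int, int], np.ndarray] = {}
    for t in range(k):
        for u in range(t):
            full, deletes = _cross_regression(
                z[:, t], z[:, u], n[:, t], n[:, u], ell, ld.m, bounds,
                h2_weight[t], h2_weight[u])
            se = _jackknife_se(deletes)
            S[t, u] = S[u, t] = full[1]
            intercepts[t, u] = intercepts[u, t] = full[0]
            intercept_se[t, u] = intercept_se[u, t] = se[0]
            rho_deletes[(t, u)] = deletes[:, 1]

    for p, (i, j) in enumerate(idx):
        delete_vech[:, p] = h2_deletes[:, i] if i == j else rho_deletes[(i, j)]
    mean = delete_vech.mean(axis=0)
    centred = delete_vech - mean
    V = (nb - 1) / nb * centred.T @ centred

    # jackknife SE of each genetic correlation (ratio re-computed per replicate)
    # JK1 form: deviations of the delete-block ratios around the full-sample
    # ratio (coincides with the mean-centred form for linear statistics and
    # is the appropriately conservative choice for the nonlinear ratio)
    rg_se = np.zeros((k, k))
    for (t, u), dels in rho_deletes.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            rg_reps = dels / np.sqrt(h2_deletes[:, t] * h2_deletes[:, u])
            rg_full = S[t, u] / np.sqrt(S[t, t] * S[u, u])
        ok = np.isfinite(rg_reps)
        if ok.sum() >= 2 and np.isfinite(rg_full):
            rep = rg_reps[ok]
            rg_se[t, u] = rg_se[u, t] = float(
                np.sqrt((len(rep) - 1) / len(rep) * ((rep - rg_full) ** 2).sum()))
        else:
            rg_se[t, u] = rg_se[u, t] = np.nan

    return GeneticCovariance(traits=[t.trait for t in aligned], S=S, V=V,
                             intercepts=intercepts, intercept_se=intercept_se,
                             h2_estimates=h2_list, rg_se=rg_se)


def smooth_psd(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to the nearest PSD matrix (+eps floor)."""
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.maximum(vals, eps)
    return vecs @ np.diag(vals) @ vecs.T


def to_liability(cov: GeneticCovariance,
                 params: dict[str, LiabilityParams]) -> GeneticCovariance:
    """Convert observed-scale (co)heritabilities to the liability scale.

    Each case-control trait contributes the square root of its conversion
    factor to every row/column it appears in, so diagonals are multiplied by
    the full factor and the genetic correlation matrix is unchanged.
    Continuous traits (absent from ``params``) carry factor 1.
    """
    if cov.scale == "liability":
        raise ValueError("covariance is already on the liability scale")
    root = np.array([np.sqrt(params[t].factor) if t in params else 1.0
                     for t in cov.traits])
    outer = np.outer(root, root)
    idx = vech_index(cov.k)
    vfac = np.array([outer[i, j] for i, j in idx])
    return GeneticCovariance(
        traits=list(cov.traits), S=cov.S * outer,
        V=cov.V * np.outer(vfac, vfac),
        intercepts=cov.intercepts.copy(), intercept_se=cov.intercept_se.copy(),
        scale="liability", h2_estimates=None,
        rg_se=None if cov.rg_se is None else cov.rg_se.copy())


@dataclass
class RgScanRecord:
    trait: str
    rg: float
    se: float
    p: float
    significant: bool


def rg_scan(focal: SumstatsTable, others: list[SumstatsTable], ld: LDScoreTable,
            n_blocks: int = 200, alpha: float = 0.05,
            m_tests: int | None = None) -> list[RgScanRecord]:
    """Genetic correlation of one focal trait against a battery of traits.

    Each pair is intersected and regressed separately; the significance flag
    applies a Bonferroni threshold alpha / m_tests (m_tests defaults to the
    number of traits scanned) to the two-sided jackknife-SE Wald p of r_g = 0.
    """
    from .sumstats import intersect
    m_tests = m_tests or len(others)
    out = []
    for other in others:
        pair = intersect([focal, other])
        cov = multivariate_ldsc(pair, ld, n_blocks=n_blocks)
        r = cov.rg()[1, 0]
        se = cov.rg_se[1, 0]
        if np.isfinite(r) and np.isfinite(se) and se > 0:
            p = float(2 * stats.norm.sf(abs(r) / se))
        elif np.isfinite(r) and se == 0:
            # degenerate zero-variance ratio (e.g. a trait against itself)
            p = 0.0 if r != 0 else 1.0
        else:
            p = np.nan
        out.append(RgScanRecord(trait=other.trait, rg=float(r), se=float(se), p=p,
                                significant=bool(np.isfinite(p) and p < alpha / m_tests)))
    return out


def neff_rg_regression(pairs: list[tuple[float, float]]):
    """OLS of pairwise genetic correlation on pair effective sample size.

    Returns (slope, adjusted R^2, two-sided slope p).  Used to check that
    estimated correlations carry no sample-size artefact."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    import statsmodels.api as sm
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.rsquared_adj), float(res.pvalues[1])
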