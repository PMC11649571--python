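"""Structural modelling of the genetic covariance matrix.

Confirmatory factor models are fitted by diagonally weighted least squares:
the half-vectorised observed covariance s = vech(S) is matched to the
model-implied sigma(theta) = vech(Lambda Psi Lambda' + Theta) by minimising

    F(theta) = (s - sigma)' D^-1 (s - sigma),   D = diag(V),

where V is the block-jackknife sampling covariance of s.  Parameter standard
errors use the full-V sandwich  (J'WJ)^-1 J'W V W J (J'WJ)^-1  with J the
Jacobian of sigma.  Factors are scaled by fixing their variances to 1;
residual variances are free (unbounded by default, so Heywood cases surface
as warnings rather than being silently truncated).

Model syntax, one relation per line::

    F1 =~ OCD + AN + TS        # free loadings
    F5 =~ ADHD + DYX
    F1 ~~ 0*F2                 # fix a factor correlation (default: all free)
    ADHD ~~ 0.1*ADHD           # fix a residual variance

Exploratory analysis extracts principal-axis factors (statsmodels) from the
genetic correlation matrix and applies a promax rotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ldsc import GeneticCovariance, smooth_psd, vech_index

logger = logging.getLogger(__name__)

__all__ = ["SemModel", "SemFit", "EfaResult", "parse_model", "saturated_model",
           "independence_model", "fit_cfa", "fit_efa", "fit_indices",
           "compare_models"]


# ---------------------------------------------------------------------------
# model specification

@dataclass
class SemModel:
    """Factor-model specification on a set of indicator traits.

    ``loadings`` maps (trait, factor) to a fixed value or None (free);
    ``factor_cov`` maps unordered factor pairs to a fixed value or None;
    ``residuals`` maps trait to a fixed value or None.  Factor variances are
    fixed to 1 for scaling.
    """

    factors: list[str]
    traits: list[str]
    loadings: dict[tuple[str, str], float | None]
    factor_cov: dict[tuple[str, str], float | None] = field(default_factory=dict)
    residuals: dict[str, float | None] = field(default_factory=dict)
    bound_residuals: bool = False

    def __post_init__(self) -> None:
        for (t, f) in self.loadings:
            if f not in self.factors:
                raise ValueError(f"loading references unknown factor {f}")
            if t not in self.traits:
                raise ValueError(f"loading references unknown trait {t}")
        loaded = {t for t, _ in self.loadings}
        orphan = set(self.traits) - loaded
        if orphan:
            raise ValueError(f"traits load on no factor: {sorted(orphan)}")
        for t in self.traits:
            self.residuals.setdefault(t, None)
        for i, f in enumerate(self.factors):
            for g in self.factors[i + 1:]:
                self.factor_cov.setdefault((f, g), None)

    @property
    def n_free(self) -> int:
        free = sum(v is None for v in self.loadings.values())
        free += sum(v is None for v in self.factor_cov.values())
        free += sum(v is None for v in self.residuals.values())
        return free

    def degrees_of_freedom(self) -> int:
        k = len(self.traits)
        return k * (k + 1) // 2 - self.n_free


def parse_model(text: str, traits: list[str] | None = None) -> SemModel:
    """Parse the one-relation-per-line model syntax into a :class:`SemModel`."""
    factors: list[str] = []
    loadings: dict[tuple[str, str], float | None] = {}
    factor_cov: dict[tuple[str, str], float | None] = {}
    residuals: dict[str, float | None] = {}
    seen_traits: list[str] = []

    def parse_term(term: str) -> tuple[float | None, str]:
        term = term.strip()
        if "*" in term:
            value, name = term.split("*", 1)
            return float(value), name.strip()
        return None, term

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~", 1)
            factor = lhs.strip()
            if factor not in factors:
                factors.append(factor)
            for term in rhs.split("+"):
                value, trait = parse_term(term)
                loadings[(trait, factor)] = value
                if trait not in seen_traits:
                    seen_traits.append(trait)
        elif "~~" in line:
            lhs, rhs = line.split("~~", 1)
            left = lhs.strip()
            value, right = parse_term(rhs)
            if left == right:
                residuals[left] = value
            else:
                factor_cov[(left, right)] = value
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")

    trait_order = traits if traits is not None else seen_traits
    unknown = [t for t in seen_traits if t not in trait_order]
    if unknown:
        raise ValueError(f"model references traits absent from the data: {unknown}")
    # normalise factor_cov keys to declaration order
    norm_cov = {}
    for (a, b), v in factor_cov.items():
        if a in factors and b in factors:
            i, j = factors.index(a), factors.index(b)
            key = (factors[min(i, j)], factors[max(i, j)])
            norm_cov[key] = v
        else:
            raise ValueError(f"covariance line references unknown factor: {a} ~~ {b}")
    return SemModel(factors=factors, traits=list(trait_order), loadings=loadings,
                    factor_cov=norm_cov, residuals=residuals)


def saturated_model(traits: list[str]) -> SemModel:
    """One single-indicator factor per trait with all factor covariances free:
    reproduces any covariance matrix exactly (chi2 = 0, df = 0)."""
    factors = [f"S_{t}" for t in traits]
    loadings = {(t, f"S_{t}"): None for t in traits}
    residuals: dict[str, float | None] = {t: 0.0 for t in traits}
    return SemModel(factors=factors, traits=list(traits), loadings=loadings,
                    residuals=residuals)


def independence_model(traits: list[str]) -> SemModel:
    """Free variances, all covariances zero — the CFI baseline."""
    factors = [f"S_{t}" for t in traits]
    loadings = {(t, f"S_{t}"): None for t in traits}
    residuals: dict[str, float | None] = {t: 0.0 for t in traits}
    cov = {}
    for i, f in enumerate(factors):
        for g in factors[i + 1:]:
            cov[(f, g)] = 0.0
    return SemModel(factors=factors, traits=list(traits), loadings=loadings,
                    factor_cov=cov, residuals=residuals)


# ---------------------------------------------------------------------------
# parameter packing and implied covariance

class _Parameterisation:
    """Maps the free-parameter vector to (Lambda, Psi, Theta) and back."""

    def __init__(self, model: SemModel):
        self.model = model
        self.k = len(model.traits)
        self.q = len(model.factors)
        self.trait_pos = {t: i for i, t in enumerate(model.traits)}
        self.fac_pos = {f: i for i, f in enumerate(model.factors)}
        self.free_loadings = [(self.trait_pos[t], self.fac_pos[f])
                              for (t, f), v in model.loadings.items() if v is None]
        self.free_cov = [(self.fac_pos[a], self.fac_pos[b])
                         for (a, b), v in model.factor_cov.items() if v is None]
        self.free_res = [self.trait_pos[t]
                         for t, v in model.residuals.items() if v is None]
        self.n_free = len(self.free_loadings) + len(self.free_cov) + len(self.free_res)

        self.lam_fixed = np.zeros((self.k, self.q))
        for (t, f), v in model.loadings.items():
            if v is not None:
                self.lam_fixed[self.trait_pos[t], self.fac_pos[f]] = v
        self.psi_fixed = np.eye(self.q)
        for (a, b), v in model.factor_cov.items():
            if v is not None:
                i, j = self.fac_pos[a], self.fac_pos[b]
                self.psi_fixed[i, j] = self.psi_fixed[j, i] = v
        self.theta_fixed = np.zeros(self.k)
        for t, v in model.residuals.items():
            if v is not None:
                self.theta_fixed[self.trait_pos[t]] = v

    def unpack(self, theta: np.ndarray):
        lam = self.lam_fixed.copy()
        psi = self.psi_fixed.copy()
        res = self.theta_fixed.copy()
        p = 0
        for (i, j) in self.free_loadings:
            lam[i, j] = theta[p]; p += 1
        for (i, j) in self.free_cov:
            psi[i, j] = psi[j, i] = theta[p]; p += 1
        for i in self.free_res:
            res[i] = theta[p]; p += 1
        return lam, psi, res

    def implied(self, theta: np.ndarray) -> np.ndarray:
        lam, psi, res = self.unpack(theta)
        return lam @ psi @ lam.T + np.diag(res)

    def implied_vech(self, theta: np.ndarray, idx) -> np.ndarray:
        sig = self.implied(theta)
        return np.array([sig[i, j] for i, j in idx])

    def jacobian(self, theta: np.ndarray, idx) -> np.ndarray:
        """Analytic d vech(Sigma) / d theta, (p*, n_free)."""
        lam, psi, _ = self.unpack(theta)
        lp = lam @ psi                      # (k, q)
        J = np.zeros((len(idx), self.n_free))
        row_of = {pair: r for r, pair in enumerate(idx)}
        p = 0
        # d Sigma / d lambda_if = e_i (Lambda Psi)_f' + (Lambda Psi)_f e_i'
        for (i, f) in self.free_loadings:
            for a in range(self.k):
                r = row_of[(max(i, a), min(i, a))]
                if a == i:
                    J[r, p] += 2 * lp[i, f]
                else:
                    J[r, p] += lp[a, f]
            p += 1
        for (f, g) in self.free_cov:
            for r, (a, b) in enumerate(idx):
                J[r, p] += lam[a, f] * lam[b, g] + lam[a, g] * lam[b, f]
            p += 1
        for i in self.free_res:
            J[row_of[(i, i)], p] = 1.0
            p += 1
        return J

    def start(self, rng: np.random.Generator, jitter: float,
              s_diag: np.ndarray) -> np.ndarray:
        """Scale-aware starting values: loadings and residuals are sized to
        the observed variances, so fits on covariance (h2) scale and on
        correlation scale start equally close to the optimum."""
        floor = np.maximum(np.abs(s_diag), np.mean(np.abs(s_diag)) + 1e-12)
        scale = np.sqrt(floor)
        lam0 = np.array([0.6 * scale[i] for i, _ in self.free_loadings])
        res0 = np.array([0.5 * floor[i] for i in self.free_res])
        theta = np.concatenate([
            lam0 * (1 + jitter * rng.standard_normal(len(lam0))),
            0.2 + jitter * rng.standard_normal(len(self.free_cov)),
            res0 * np.abs(1 + jitter * rng.standard_normal(len(res0))),
        ])
        return theta

    def bounds(self, s_diag: np.ndarray):
        """Loose sanity bounds keyed to the observed variances: standardized
        loadings within +-3, residuals within +-5 observed variances.  These
        exclude the degenerate huge-loading/negative-residual optima without
        constraining any plausible solution.  Noisy (possibly negative)
        observed variances are floored at the panel-average magnitude."""
        floor = np.maximum(np.abs(s_diag), np.mean(np.abs(s_diag)) + 1e-12)
        scale = np.sqrt(floor)
        b: list[tuple[float | None, float | None]] = []
        b += [(-3 * scale[i], 3 * scale[i]) for i, _ in self.free_loadings]
        b += [(-0.999, 0.999)] * len(self.free_cov)
        b += [(0.0 if self.model.bound_residuals else -5 * floor[i],
               5 * floor[i]) for i in self.free_res]
        return b


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SemFit:
    model: SemModel
    cov: GeneticCovariance
    theta: np.ndarray
    se: np.ndarray
    loadings: np.ndarray          # standardized (k, q)
    factor_corr: np.ndarray       # (q, q)
    residuals: np.ndarray         # standardized (k,)
    chisq: float
    df: int
    chisq_baseline: float
    df_baseline: int
    aic: float
    cfi: float
    srmr: float
    converged: bool
    warnings: list[str] = field(default_factory=list)
    objective: float = np.nan

    def parameter_table(self):
        """Long-format (parameter, estimate, se) table of the free parameters."""
        import pandas as pd
        par = self.model
        rows = []
        p = 0
        for (t, f), v in par.loadings.items():
            if v is None:
                rows.append((f"{f} =~ {t}", self.theta[p], self.se[p])); p += 1
        for (a, b), v in par.factor_cov.items():
            if v is None:
                rows.append((f"{a} ~~ {b}", self.theta[p], self.se[p])); p += 1
        for t, v in par.residuals.items():
            if v is None:
                rows.append((f"{t} ~~ {t}", self.theta[p], self.se[p])); p += 1
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


def _dwls_objective(par: _Parameterisation, s: np.ndarray, w: np.ndarray, idx):
    def fun(theta):
        resid = par.implied_vech(theta, idx) - s
        return float(resid @ (w * resid))

    def grad(theta):
        resid = par.implied_vech(theta, idx) - s
        return 2.0 * par.jacobian(theta, idx).T @ (w * resid)

    return fun, grad


def fit_cfa(cov: GeneticCovariance, model: SemModel, n_starts: int = 5,
            seed: int = 0, tol: float = 1e-10) -> SemFit:
    """Fit a confirmatory factor model to a genetic covariance matrix by DWLS.

    Runs ``n_starts`` jittered quasi-Newton starts (deterministic under
    ``seed``) and keeps the best optimum.  Non-convergence of every start is
    flagged on the returned fit, never silent.
    """
    missing = [t for t in model.traits if t not in cov.traits]
    if missing:
        raise ValueError(f"model traits absent from covariance: {missing}")
    cov_m = cov.subset(model.traits) if list(cov.traits) != list(model.traits) else cov
    idx = vech_index(len(model.traits))
    s = cov_m.vech()
    dvar = np.maximum(np.diag(cov_m.V), 1e-12)
    w = 1.0 / dvar

    par = _Parameterisation(model)
    if par.n_free > len(idx):
        raise ValueError("model is not identified (more free parameters than moments)")
    fun, grad = _dwls_objective(par, s, w, idx)

    rng = np.random.default_rng(seed)
    s_diag = np.diag(cov_m.S)
    best = None
    converged = False
    for start in range(n_starts):
        theta0 = par.start(rng, jitter=0.0 if start == 0 else 0.15,
                           s_diag=s_diag)
        res = optimize.minimize(fun, theta0, jac=grad, method="L-BFGS-B",
                                bounds=par.bounds(s_diag),
                                options={"maxiter": 5000, "maxfun": 50000,
                                         "ftol": tol, "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)
    theta = best.x
    warn: list[str] = []
    if not converged:
        warn.append("no optimizer start reported convergence")
        logger.warning("CFA did not converge: %s", best.message)

    lam, psi, resid = par.unpack(theta)
    if (resid < 0).any() and not model.bound_residuals:
        heywood = [model.traits[i] for i in np.where(resid < 0)[0]]
        warn.append(f"Heywood case: negative residual variance for {heywood}")

    # sandwich SEs with the full jackknife V
    J = par.jacobian(theta, idx)
    JW = J.T * w
    bread = np.linalg.pinv(JW @ J)
    meat = JW @ cov_m.V @ JW.T
    se = np.sqrt(np.maximum(np.diag(bread @ meat @ bread), 0.0))

    # standardized solution: scale indicators by model-implied sd
    sigma = par.implied(theta)
    d = np.sqrt(np.maximum(np.abs(np.diag(sigma)), 1e-300))
    lam_std = lam / d[:, None]
    resid_std = resid / d ** 2

    fit = SemFit(model=model, cov=cov_m, theta=theta, se=se, loadings=lam_std,
                 factor_corr=psi, residuals=resid_std, chisq=np.nan, df=0,
                 chisq_baseline=np.nan, df_baseline=0, aic=np.nan, cfi=np.nan,
                 srmr=np.nan, converged=converged, warnings=warn,
                 objective=float(best.fun))
    chisq, aic, cfi, srmr, chb, dfb = fit_indices(fit, cov_m)
    fit.chisq, fit.aic, fit.cfi, fit.srmr = chisq, aic, cfi, srmr
    fit.df = model.degrees_of_freedom()
    fit.chisq_baseline, fit.df_baseline = chb, dfb
    return fit


def _v_quadratic(resid: np.ndarray, V: np.ndarray) -> float:
    """Residual discrepancy e' V^+ e with the full sampling covariance."""
    Vs = smooth_psd(V, eps=1e-12)
    return float(resid @ np.linalg.pinv(Vs) @ resid)


def fit_indices(fit: SemFit, cov: GeneticCovariance):
    """Model chi2 (full-V weighted discrepancy), AIC, CFI and SRMR.

    chi2  = e' V^+ e with e the vech residual;
    AIC   = chi2 + 2 * n_free;
    CFI   = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0)
            against the free-variances independence baseline;
    SRMR  = RMS of the residual correlation matrix (lower triangle + diagonal).
    """
    model = fit.model
    cov_m = cov.subset(model.traits) if list(cov.traits) != list(model.traits) else cov
    idx = vech_index(len(model.traits))
    s = cov_m.vech()
    par = _Parameterisation(model)
    sigma_vech = par.implied_vech(fit.theta, idx)
    resid = s - sigma_vech
    chisq = _v_quadratic(resid, cov_m.V)
    df_m = model.degrees_of_freedom()

    # independence baseline: variances match observed, covariances zero
    base_resid = np.array([0.0 if i == j else cov_m.S[i, j] for i, j in idx])
    chisq_b = _v_quadratic(base_resid, cov_m.V)
    df_b = len(model.traits) * (len(model.traits) - 1) // 2

    num = max(chisq - df_m, 0.0)
    den = max(chisq_b - df_b, chisq - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    cfi = float(np.clip(cfi, 0.0, 1.0))

    # |diag|: null-ish panels can carry small negative variance estimates
    d = np.sqrt(np.maximum(np.abs(np.diag(cov_m.S)), 1e-300))
    sigma = par.implied(fit.theta)
    std_resid = [(cov_m.S[i, j] - sigma[i, j]) / (d[i] * d[j]) for i, j in idx]
    srmr = float(np.sqrt(np.mean(np.square(std_resid))))

    aic = chisq + 2 * par.n_free
    return float(chisq), float(aic), cfi, srmr, float(chisq_b), df_b


def compare_models(fits: list[SemFit]):
    """Rank fits on one covariance matrix by ascending AIC (ties keep input
    order); returns a DataFrame with delta-AIC, CFI and SRMR side by side."""
    import pandas as pd
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ref = fits[0].cov
    for f in fits[1:]:
        if sorted(f.cov.traits) != sorted(ref.traits):
            raise ValueError("fits are not on the same covariance object")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, i))
    best = fits[order[0]].aic
    rows = [{"model": i, "aic": fits[i].aic, "delta_aic": fits[i].aic - best,
             "chisq": fits[i].chisq, "df": fits[i].df,
             "cfi": fits[i].cfi, "srmr": fits[i].srmr,
             "converged": fits[i].converged} for i in order]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exploratory analysis

@dataclass
class EfaResult:
    n_factors: int
    loadings: np.ndarray          # promax pattern matrix (k, q)
    factor_corr: np.ndarray       # (q, q)
    variance_explained: float     # proportion of total variance
    clusters: dict[str, int]      # trait -> max-|loading| factor


def _varimax(A: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation matrix T (A @ T is the rotated pattern)."""
    k, q = A.shape
    T = np.eye(q)
    d = 0.0
    for _ in range(max_iter):
        L = A @ T
        u, s, vt = np.linalg.svd(
            A.T @ (L ** 3 - (L * (L ** 2).sum(axis=0)) / k))
        T = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return T


def _promax(A: np.ndarray, power: int = 4):
    """Promax rotation (Hendrickson-White): varimax followed by an oblique
    Procrustes fit to the powered target.  Returns (pattern, factor_corr)."""
    T = _varimax(A)
    V = A @ T
    # column sign convention: dominant direction positive
    signs = np.sign(V.sum(axis=0))
    signs[signs == 0] = 1.0
    V = V * signs
    target = np.abs(V) ** power * np.sign(V)
    coef, *_ = np.linalg.lstsq(V, target, rcond=None)
    # normalise so implied factor variances are 1
    gram_inv = np.linalg.pinv(coef.T @ coef)
    coef = coef @ np.diag(np.sqrt(np.maximum(np.diag(gram_inv), 1e-300)))
    pattern = V @ np.linalg.pinv(coef).T
    phi = coef.T @ coef
    return pattern, phi


def fit_efa(R: np.ndarray, k: int, trait_names: list[str] | None = None,
            method: str = "ml") -> EfaResult:
    """Exploratory factor analysis of a genetic correlation matrix.

    Maximum-likelihood extraction (statsmodels; principal-axis fallback when
    ML fails to converge) of ``k`` factors followed by a promax rotation;
    reports the proportion of total variance explained and each trait's
    max-loading cluster assignment.
    """
    R = np.asarray(R, float)
    n = R.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"factor count {k} out of range for {n} traits")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    R = smooth_psd(R)
    dscale = np.sqrt(np.diag(R))
    R = R / np.outer(dscale, dscale)  # re-normalise diagonal after smoothing

    from statsmodels.multivariate.factor import Factor
    A = None
    for extract in ([method, "pa"] if method != "pa" else ["pa"]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fa = Factor(corr=R, n_factor=k, method=extract, smc=True).fit()
                cand = np.asarray(fa.loadings)
            except Exception:
                continue
        if np.all(np.isfinite(cand)):
            A = cand
            break
    if A is None:
        raise ValueError(f"extraction of {k} factors failed (Heywood/rotation "
                         "instability); reduce k or smooth the input")
    if k == 1:
        pattern, phi = A.copy(), np.eye(1)
        sign = np.sign(pattern.sum()) or 1.0
        pattern *= sign
    else:
        pattern, phi = _promax(A)

    # communalities under the oblique solution: diag(P Phi P')
    communal = np.clip(np.diag(pattern @ phi @ pattern.T), 0.0, None)
    var_explained = float(communal.sum() / n)
    names = trait_names or [f"trait{i}" for i in range(n)]
    clusters = {names[i]: int(np.argmax(np.abs(pattern[i]))) for i in range(n)}
    return EfaResult(n_factors=k, loadings=pattern, factor_corr=phi,
                     variance_explained=var_explained, clusters=clusters)
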