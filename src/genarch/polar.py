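"""Cross-trait pleiotropy detection via polar coordinates.

For two traits the signed z-scores of each SNP are whitened against the null
cross-trait correlation c (sample overlap + vertical pleiotropy, estimated
from the cross-trait LDSC intercept), then expressed in polar form:

    r     = sqrt(u1^2 + u2^2)          overall effect size,
    theta = arctan(|u2| / |u1|)        degree of sharedness in [0, pi/2],

with theta = pi/4 meaning an equal effect on both traits and 0 or pi/2 a
single-trait effect.  p_r is the chi-square(2df) survival probability
exp(-r^2/2); p_theta is the probability, under a single-trait-effect null
conditional on the observed r, of an angle at least as close to pi/4.  SNPs
significant on both Benjamini-Hochberg q-values are clumped into
LD-independent lead SNPs and merged genomic risk loci, with the long-range-LD
MHC region always collapsed to a single locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["whiten", "estimate_null_correlation", "polar_transform",
           "polar_pvalues", "bh_fdr", "polar_table", "select_shared",
           "ClumpConfig", "Locus", "LDMatrix", "clump", "genomic_inflation"]

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

#: GRCh37 MHC interval used for the one-locus rule
MHC_DEFAULT = (6, 25_000_000, 34_000_000)


def whiten(z1: np.ndarray, z2: np.ndarray, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Decorrelate a z-score pair with inverse-Cholesky whitening.

    With L the lower Cholesky factor of [[1, c], [c, 1]], returns
    L^-1 (z1, z2): u1 = z1, u2 = (z2 - c*z1)/sqrt(1-c^2).  Under the null the
    whitened pair has identity covariance."""
    if not abs(c) < 1:
        raise ValueError(f"null correlation must satisfy |c| < 1, got {c}")
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    u1 = z1
    u2 = (z2 - c * z1) / np.sqrt(1.0 - c * c)
    return u1, u2


def estimate_null_correlation(z1: np.ndarray, z2: np.ndarray,
                              intercept: float | None = None,
                              z_max: float = 1.96) -> float:
    """Null cross-trait correlation: the cross-trait LDSC intercept when
    available, else the empirical correlation of null-looking SNPs
    (both |z| < ``z_max``)."""
    if intercept is not None:
        return float(np.clip(intercept, -0.999, 0.999))
    mask = (np.abs(z1) < z_max) & (np.abs(z2) < z_max)
    if mask.sum() < 100:
        raise ValueError("too few null SNPs to estimate the correlation")
    return float(np.clip(np.corrcoef(z1[mask], z2[mask])[0, 1], -0.999, 0.999))


def polar_transform(u1: np.ndarray, u2: np.ndarray):
    """(r, theta) of whitened pairs; theta folded to [0, pi/2].

    (0, 0) pairs have no defined angle: theta is NaN there and callers flag
    the record.  Sign concordance of (u1, u2) is reported separately."""
    u1 = np.asarray(u1, float)
    u2 = np.asarray(u2, float)
    r = np.hypot(u1, u2)
    with np.errstate(invalid="ignore"):
        theta = np.arctan2(np.abs(u2), np.abs(u1))
    theta = np.where(r == 0, np.nan, theta)
    concordant = np.sign(u1) == np.sign(u2)
    return r, theta, concordant


# ---------------------------------------------------------------------------
# p-values

def p_radius(r: np.ndarray) -> np.ndarray:
    """P(chi2_2 > r^2) = exp(-r^2/2): radial p under the complete null."""
    r = np.asarray(r, float)
    return np.exp(-0.5 * r * r)


def _theta_distance_samples(r: float, rng: np.random.Generator,
                            n_draws: int) -> np.ndarray:
    """Sorted |theta - pi/4| samples under the single-trait-effect null at
    radius r: signal r on one axis plus standard bivariate noise, antithetic."""
    half = n_draws // 2
    e = rng.standard_normal((half, 2))
    e = np.vstack([e, -e])
    # by the fold symmetry the phi = pi/2 axis gives the mirrored distribution
    x = r + e[:, 0]
    y = e[:, 1]
    th = np.arctan2(np.abs(y), np.abs(x))
    return np.sort(np.abs(th - np.pi / 4))


def polar_pvalues(r: np.ndarray, theta: np.ndarray, seed: int = 0,
                  n_draws: int = 100_000, grid_size: int = 256):
    """(p_r, p_theta) for arrays of polar records.

    p_theta is Monte-Carlo: under the null a SNP of radius r acts on a single
    trait, so the observed angle scatters around 0 (or pi/2); the p-value is
    the probability of an angle at least as close to pi/4 as observed,
    conditional on r.  The null is simulated once per radius on a grid
    (``grid_size`` radii, ``n_draws`` antithetic draws each, deterministic
    under ``seed``) and each SNP is interpolated between the two bracketing
    grid radii.  Undefined angles (r = 0) get p_theta = NaN.
    """
    r = np.asarray(r, float)
    theta = np.asarray(theta, float)
    p_r = p_radius(r)
    ok = np.isfinite(theta) & (r > 0)
    p_theta = np.full(r.shape, np.nan)
    if ok.sum() == 0:
        return p_r, p_theta

    rng = np.random.default_rng(seed)
    d_obs = np.abs(theta[ok] - np.pi / 4)
    r_ok = r[ok]
    uniq = np.unique(r_ok)
    if len(uniq) <= grid_size:
        grid = uniq
    else:
        grid = np.quantile(r_ok, np.linspace(0, 1, grid_size))
        grid = np.unique(grid)
    # P(d_sim <= d_obs) per grid radius via sorted samples + searchsorted
    tail = np.empty((len(grid), len(d_obs)))
    for gi, rg in enumerate(grid):
        samples = _theta_distance_samples(float(rg), rng, n_draws)
        tail[gi] = np.searchsorted(samples, d_obs, side="right") / len(samples)
    if len(grid) == 1:
        p_ok = tail[0]
    else:
        gi = np.clip(np.searchsorted(grid, r_ok) - 1, 0, len(grid) - 2)
        w = (r_ok - grid[gi]) / np.maximum(grid[gi + 1] - grid[gi], 1e-300)
        w = np.clip(w, 0.0, 1.0)
        cols = np.arange(len(d_obs))
        p_ok = (1 - w) * tail[gi, cols] + w * tail[gi + 1, cols]
    p_theta[ok] = np.clip(p_ok, 0.0, 1.0)
    return p_r, p_theta


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order (NaNs pass through)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def polar_table(df1: pd.DataFrame, df2: pd.DataFrame,
                intercept: float | None = None, seed: int = 0,
                n_draws: int = 100_000) -> pd.DataFrame:
    """Full per-SNP polar analysis of two aligned sumstats frames.

    Frames must share SNP order (intersect + harmonize first).  Returns
    columns SNP, CHR, BP, u1, u2, r, theta, p_r, p_theta, q_r, q_theta."""
    if not np.array_equal(df1["SNP"].to_numpy(), df2["SNP"].to_numpy()):
        raise ValueError("frames must share an identical SNP order")
    z1 = df1["Z"].to_numpy(float)
    z2 = df2["Z"].to_numpy(float)
    c = estimate_null_correlation(z1, z2, intercept=intercept)
    u1, u2 = whiten(z1, z2, c)
    r, theta, concordant = polar_transform(u1, u2)
    p_r, p_theta = polar_pvalues(r, theta, seed=seed, n_draws=n_draws)
    out = pd.DataFrame({
        "SNP": df1["SNP"], "CHR": df1["CHR"], "BP": df1["BP"],
        "u1": u1, "u2": u2, "r": r, "theta": theta,
        "concordant": concordant,
        "p_r": p_r, "p_theta": p_theta,
        "q_r": bh_fdr(p_r), "q_theta": bh_fdr(p_theta),
    })
    out.attrs["null_correlation"] = c
    return out


def select_shared(records: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """SNPs significant for both effect size and sharedness
    (q_r < q_max AND q_theta < q_max)."""
    keep = (records["q_r"] < q_max) & (records["q_theta"] < q_max)
    return records.loc[keep.fillna(False)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clumping

@dataclass
class ClumpConfig:
    r2_threshold: float = 0.4
    max_distance_kb: float = 500.0
    lead_p_max: float = 5e-8
    member_p_max: float = 5e-2
    mhc_interval: tuple[int, int, int] = MHC_DEFAULT

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2 threshold must be in (0, 1]")
        if self.max_distance_kb <= 0:
            raise ValueError("max distance must be positive")


@dataclass
class Locus:
    chrom: int
    start: int
    end: int
    leads: list[str]
    members: list[str]
    best_p: float
    is_mhc: bool = False

    def __post_init__(self) -> None:
        assert self.start <= self.end
        assert all(l in self.members for l in self.leads)


class LDMatrix:
    """Pairwise r-squared provider.

    Backed either by a square matrix + SNP index (toy panels) or a sparse
    pair table (chrom/snpA/snpB/r2).  Unknown pairs count as r2 = 0 and are
    tallied on ``misses``."""

    def __init__(self, snp_ids: list[str] | None = None,
                 matrix: np.ndarray | None = None,
                 pairs: pd.DataFrame | None = None):
        self.misses = 0
        self._index = None
        self._matrix = None
        self._pairs: dict[tuple[str, str], float] = {}
        if matrix is not None:
            if snp_ids is None or len(snp_ids) != matrix.shape[0]:
                raise ValueError("square-matrix LD needs matching snp_ids")
            self._index = {s: i for i, s in enumerate(snp_ids)}
            self._matrix = np.asarray(matrix, float)
        elif pairs is not None:
            cols = {c.upper(): c for c in pairs.columns}
            a, b, r2 = cols["SNPA"], cols["SNPB"], cols["R2"]
            for row in pairs.itertuples(index=False):
                key = tuple(sorted((str(getattr(row, a)), str(getattr(row, b)))))
                self._pairs[key] = float(getattr(row, r2))
        else:
            raise ValueError("provide either a matrix or a pair table")

    @classmethod
    def from_matrix_file(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(snp_ids=list(df.index.astype(str)), matrix=df.to_numpy(float))

    @classmethod
    def from_pair_file(cls, path) -> "LDMatrix":
        return cls(pairs=pd.read_csv(path, sep=None, engine="python"))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if self._matrix is not None:
            ia, ib = self._index.get(a), self._index.get(b)
            if ia is None or ib is None:
                self.misses += 1
                return 0.0
            return float(self._matrix[ia, ib])
        val = self._pairs.get(tuple(sorted((a, b))))
        if val is None:
            self.misses += 1
            return 0.0
        return val


def clump(selected: pd.DataFrame, ld: LDMatrix,
          cfg: ClumpConfig | None = None,
          p_column: str = "p_r") -> tuple[list[str], list[Locus]]:
    """Greedy LD clumping of significant SNPs into lead SNPs and risk loci.

    Walking SNPs by ascending p: each unassigned SNP below ``lead_p_max``
    founds a clump; unassigned SNPs below ``member_p_max`` within
    ``max_distance_kb`` and with r2 >= ``r2_threshold`` of the lead join it.
    Clumps with overlapping intervals merge into one locus, and loci touching
    the MHC interval merge into a single MHC locus.
    """
    cfg = cfg or ClumpConfig()
    df = selected.sort_values([p_column, "SNP"], kind="mergesort")
    snp = df["SNP"].to_numpy(str)
    chrom = df["CHR"].to_numpy(int)
    bp = df["BP"].to_numpy(int)
    p = df[p_column].to_numpy(float)

    max_bp = cfg.max_distance_kb * 1000.0
    assigned = np.zeros(len(df), bool)
    clumps: list[dict] = []
    for i in range(len(df)):
        if assigned[i] or not (p[i] < cfg.lead_p_max):
            continue
        assigned[i] = True
        members = [i]
        near = np.where(~assigned & (chrom == chrom[i])
                        & (np.abs(bp - bp[i]) <= max_bp)
                        & (p < cfg.member_p_max))[0]
        for j in near:
            if ld.r2(snp[i], snp[j]) >= cfg.r2_threshold:
                assigned[j] = True
                members.append(int(j))
        clumps.append({"lead": i, "members": members})
    if ld.misses:
        logger.info("clump: %d LD pairs missing from provider (treated as r2=0)",
                    ld.misses)

    # merge overlapping clump intervals into loci
    intervals = []
    for c in clumps:
        m = c["members"]
        intervals.append({
            "chrom": int(chrom[c["lead"]]),
            "start": int(bp[m].min()), "end": int(bp[m].max()),
            "leads": [snp[c["lead"]]], "members": [snp[j] for j in m],
            "best_p": float(p[c["lead"]]),
        })
    intervals.sort(key=lambda x: (x["chrom"], x["start"], x["end"]))
    merged: list[dict] = []
    for iv in intervals:
        if merged and iv["chrom"] == merged[-1]["chrom"] \
                and iv["start"] <= merged[-1]["end"]:
            last = merged[-1]
            last["end"] = max(last["end"], iv["end"])
            last["leads"] += iv["leads"]
            last["members"] += iv["members"]
            last["best_p"] = min(last["best_p"], iv["best_p"])
        else:
            merged.append(dict(iv))

    # MHC one-locus rule
    mhc_chr, mhc_lo, mhc_hi = cfg.mhc_interval
    in_mhc = [iv for iv in merged
              if iv["chrom"] == mhc_chr and iv["start"] <= mhc_hi and iv["end"] >= mhc_lo]
    out = [iv for iv in merged if iv not in in_mhc]
    loci = [Locus(iv["chrom"], iv["start"], iv["end"], iv["leads"],
                  iv["members"], iv["best_p"]) for iv in out]
    if in_mhc:
        loci.append(Locus(
            mhc_chr, min(iv["start"] for iv in in_mhc),
            max(iv["end"] for iv in in_mhc),
            [l for iv in in_mhc for l in iv["leads"]],
            [m for iv in in_mhc for m in iv["members"]],
            min(iv["best_p"] for iv in in_mhc), is_mhc=True))
    loci.sort(key=lambda L: (L.chrom, L.start))
    leads = [l for L in loci for l in L.leads]
    return leads, loci


def loci_to_bed(loci: list[Locus]) -> pd.DataFrame:
    """0-based half-open BED intervals for a locus list."""
    return pd.DataFrame({
        "chrom": [f"chr{L.chrom}" for L in loci],
        "start": [L.start - 1 for L in loci],
        "end": [L.end for L in loci],
        "name": [";".join(L.leads) for L in loci],
    })


# ---------------------------------------------------------------------------
# inflation diagnostics

def genomic_inflation(p: np.ndarray | None = None,
                      chisq: np.ndarray | None = None,
                      cases: float | None = None,
                      controls: float | None = None) -> dict:
    """Genomic inflation factor lambda = median(chi2)/0.45494 and, when
    case/control counts are given, its lambda_1000 rescaling
    1 + (lambda-1) * (1/cases + 1/controls) * 500.

    The equal-weight form (cases = controls = n_total/2) is also reported so
    quantitative designs get a defined value."""
    if chisq is None:
        if p is None:
            raise ValueError("provide p-values or chi-square statistics")
        p = np.asarray(p, float)
        p = p[np.isfinite(p)]
        if len(p) < 100:
            raise ValueError("need at least 100 statistics")
        chisq = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    else:
        chisq = np.asarray(chisq, float)
        chisq = chisq[np.isfinite(chisq)]
        if len(chisq) < 100:
            raise ValueError("need at least 100 statistics")
    lam = float(np.median(chisq) / _CHI2_MEDIAN_1DF)
    out = {"lambda": lam, "lambda_1000": None, "lambda_1000_equal": None}
    if cases and controls:
        out["lambda_1000"] = 1.0 + (lam - 1.0) * (1.0 / cases + 1.0 / controls) * 500.0
        n = cases + controls
        out["lambda_1000_equal"] = 1.0 + (lam - 1.0) * (2.0 / (n / 2)) * 500.0
    return out
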