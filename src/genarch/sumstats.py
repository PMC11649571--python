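"""Reading, harmonisation, QC filtering and intersection of GWAS summary statistics.

The canonical in-memory container is :class:`SumstatsTable`, a thin wrapper
around a pandas DataFrame with columns ``SNP, CHR, BP, A1, A2, Z, N, FREQ,
INFO`` sorted by (CHR, BP).  All downstream regressions consume the signed
per-SNP z-score ``Z`` and the per-SNP sample size ``N`` (effective N for
case-control designs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "FREQ", "INFO"]

#: common header aliases accepted without an explicit column map
_ALIASES = {
    "SNP": ["SNP", "RSID", "RS", "MARKERNAME", "ID", "VARIANT_ID"],
    "CHR": ["CHR", "CHROM", "CHROMOSOME"],
    "BP": ["BP", "POS", "POSITION", "BASE_PAIR_LOCATION"],
    "A1": ["A1", "EA", "EFFECT_ALLELE", "ALLELE1"],
    "A2": ["A2", "OA", "NEA", "OTHER_ALLELE", "ALLELE2", "ALLELE0"],
    "Z": ["Z", "ZSCORE", "Z_SCORE", "ZSTAT"],
    "BETA": ["BETA", "B", "EFFECT", "LOG_ODDS", "LOGOR"],
    "SE": ["SE", "STDERR", "STANDARD_ERROR"],
    "N": ["N", "NEFF", "N_EFF", "TOTALN", "SAMPLESIZE"],
    "FREQ": ["FREQ", "FRQ", "AF", "EAF", "MAF", "A1FREQ", "FREQ1"],
    "INFO": ["INFO", "IMPINFO", "RSQ", "INFO_SCORE"],
}

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def effective_n(cases: float, controls: float) -> float:
    """Effective sample size 4 / (1/cases + 1/controls) of a case-control design."""
    if cases <= 0 or controls <= 0:
        raise ValueError(f"case/control counts must be positive, got {cases}, {controls}")
    return 4.0 / (1.0 / cases + 1.0 / controls)


@dataclass
class SumstatsTable:
    """Harmonised per-SNP association records for one trait."""

    trait: str
    df: pd.DataFrame
    cases: int | None = None
    controls: int | None = None
    prevalence: float | None = None
    #: per-category row-drop tallies accumulated by the munge steps
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sumstats table missing columns: {missing}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def is_case_control(self) -> bool:
        return self.cases is not None and self.controls is not None

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.df["SNP"])

    def _replace(self, df: pd.DataFrame, **log_updates) -> "SumstatsTable":
        log = dict(self.log)
        for k, v in log_updates.items():
            log[k] = log.get(k, 0) + v
        return SumstatsTable(self.trait, df, self.cases, self.controls,
                             self.prevalence, log)


@dataclass
class LDScoreTable:
    """Per-SNP LD scores (univariate L2) plus the SNP count M of the
    heritability denominator (conventionally the MAF>5% reference count)."""

    df: pd.DataFrame  # columns SNP, L2 (CHR/BP optional)
    m: float

    def __post_init__(self) -> None:
        if "SNP" not in self.df.columns or "L2" not in self.df.columns:
            raise ValueError("LD-score table needs SNP and L2 columns")
        if self.m <= 0:
            raise ValueError("M must be positive")
        if (self.df["L2"] < 0).any():
            raise ValueError("negative LD scores")


def _normalise_chrom(values: pd.Series) -> pd.Series:
    s = values.astype(str).str.upper().str.replace("CHR", "", regex=False)
    s = s.replace({"X": "23", "Y": "24", "MT": "25", "M": "25"})
    return pd.to_numeric(s, errors="coerce")


def _resolve_columns(header: list[str], column_map: dict | None) -> dict:
    """Map canonical names to actual file columns via explicit map then aliases."""
    upper = {c.upper(): c for c in header}
    out = {}
    column_map = column_map or {}
    for canon, aliases in _ALIASES.items():
        if canon in column_map:
            if column_map[canon] not in header:
                raise ValueError(f"mapped column {column_map[canon]!r} for {canon} "
                                 f"not present in file header")
            out[canon] = column_map[canon]
            continue
        for a in aliases:
            if a in upper:
                out[canon] = upper[a]
                break
    return out


def read_sumstats(path, column_map: dict | None = None, trait: str | None = None,
                  cases: int | None = None, controls: int | None = None,
                  prevalence: float | None = None,
                  default_n: float | None = None) -> SumstatsTable:
    """Read one delimited summary-statistics file into a :class:`SumstatsTable`.

    ``Z`` is derived as beta/se when the file carries effect and standard-error
    columns but no z column.  Rows failing the record invariants (identical
    alleles, non-ACGT alleles, unparseable numerics, out-of-range FREQ/INFO)
    are skipped with per-reason tallies in ``table.log``.

    Parameters
    ----------
    column_map
        Optional mapping from canonical names (``SNP, CHR, BP, A1, A2, Z,
        BETA, SE, N, FREQ, INFO``) to the file's header names; common aliases
        are auto-detected otherwise.
    default_n
        Per-SNP N to use when the file has no N column.  For case-control
        designs with ``cases``/``controls`` given, the effective sample size
        4/(1/cases + 1/controls) is the fallback.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = _resolve_columns(list(raw.columns), column_map)

    mandatory = ["SNP", "CHR", "BP", "A1", "A2"]
    missing = [c for c in mandatory if c not in cols]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    if "Z" not in cols and not ("BETA" in cols and "SE" in cols):
        raise ValueError(f"no Z column and no (BETA, SE) pair in {path}")
    if "N" not in cols and default_n is None and not (cases and controls):
        raise ValueError(f"no N column in {path} and no fallback sample size given")

    df = pd.DataFrame({"SNP": raw[cols["SNP"]].astype(str)})
    df["CHR"] = _normalise_chrom(raw[cols["CHR"]])
    df["BP"] = pd.to_numeric(raw[cols["BP"]], errors="coerce")
    df["A1"] = raw[cols["A1"]].astype(str).str.upper()
    df["A2"] = raw[cols["A2"]].astype(str).str.upper()
    if "Z" in cols:
        df["Z"] = pd.to_numeric(raw[cols["Z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw[cols["BETA"]], errors="coerce")
        se = pd.to_numeric(raw[cols["SE"]], errors="coerce")
        df["Z"] = beta / se.where(se > 0)
    if "N" in cols:
        df["N"] = pd.to_numeric(raw[cols["N"]], errors="coerce")
    else:
        fallback = default_n if default_n is not None else effective_n(cases, controls)
        df["N"] = fallback
    df["FREQ"] = pd.to_numeric(raw[cols["FREQ"]], errors="coerce") if "FREQ" in cols else np.nan
    df["INFO"] = pd.to_numeric(raw[cols["INFO"]], errors="coerce") if "INFO" in cols else np.nan

    log: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        n = int(mask.sum())
        if n:
            log[reason] = log.get(reason, 0) + n
            logger.info("%s: dropped %d rows (%s)", path, n, reason)
        nonlocal_df[0] = nonlocal_df[0].loc[~mask]

    nonlocal_df = [df]
    d = nonlocal_df[0]
    drop(d["SNP"].isna() | d["CHR"].isna() | d["BP"].isna() | ~np.isfinite(d["Z"]),
         "unparseable numeric")
    d = nonlocal_df[0]
    drop(~d["A1"].isin(list(_VALID_ALLELES)) | ~d["A2"].isin(list(_VALID_ALLELES)),
         "non-ACGT allele")
    d = nonlocal_df[0]
    drop(d["A1"] == d["A2"], "invalid alleles")
    d = nonlocal_df[0]
    drop(~(d["N"] > 0), "non-positive N")
    d = nonlocal_df[0]
    freq_bad = d["FREQ"].notna() & ((d["FREQ"] < 0) | (d["FREQ"] > 1))
    drop(freq_bad, "frequency out of range")
    d = nonlocal_df[0]
    drop(d["SNP"].duplicated(keep="first"), "duplicate snp_id")

    out = nonlocal_df[0].sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    out["CHR"] = out["CHR"].astype(int)
    out["BP"] = out["BP"].astype(int)
    n_skipped = sum(log.values())
    if n_skipped:
        logger.info("%s: %d of %d rows skipped", path, n_skipped, len(raw))
    return SumstatsTable(trait or str(path), out, cases, controls, prevalence, log)


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write the canonical tab-delimited dialect (round-trips bit-identically)."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_reference(path) -> pd.DataFrame:
    """Read a variant reference table (SNP, CHR, BP, A1, A2, FREQ)."""
    ref = pd.read_csv(path, sep=None, engine="python")
    ref.columns = [c.upper() for c in ref.columns]
    need = {"SNP", "A1", "A2"}
    if not need.issubset(ref.columns):
        raise ValueError(f"reference table must carry columns {sorted(need)}")
    ref["A1"] = ref["A1"].astype(str).str.upper()
    ref["A2"] = ref["A2"].astype(str).str.upper()
    if ref["SNP"].duplicated().any():
        ref = ref.drop_duplicates("SNP", keep="first")
    return ref


def read_ldscores(scores_path, m: float | None = None, m_path=None) -> LDScoreTable:
    """Read a flat LD-score file (columns CHR, SNP, BP, L2).

    M comes from, in order of precedence: the ``m`` argument, a companion
    count file (single number, as written by the standard score distributions),
    or the row count of the score file itself.
    """
    df = pd.read_csv(scores_path, sep=None, engine="python")
    df.columns = [c.upper() for c in df.columns]
    if m is None and m_path is not None:
        with open(m_path) as fh:
            m = float(fh.read().split()[0])
    if m is None:
        m = float(len(df))
    return LDScoreTable(df, m)


def write_ldscores(ld: LDScoreTable, scores_path, m_path=None) -> None:
    ld.df.to_csv(scores_path, sep="\t", index=False, float_format="%.10g")
    if m_path is not None:
        with open(m_path, "w") as fh:
            fh.write(f"{ld.m:.0f}\n")


def harmonize(table: SumstatsTable, ref: pd.DataFrame) -> SumstatsTable:
    """Align effect alleles to a reference orientation.

    Records matching the reference (A1, A2) are kept as-is; records with the
    alleles swapped are kept with Z negated and FREQ reflected; strand flips
    (complement matches) are re-oriented likewise.  Strand-ambiguous A/T and
    C/G records and allele mismatches are dropped.  Idempotent: a second pass
    over already-aligned records changes nothing.
    """
    if table.n_snps == 0:
        raise ValueError("cannot harmonize an empty table")
    merged = table.df.merge(ref[["SNP", "A1", "A2"]].rename(
        columns={"A1": "REF_A1", "A2": "REF_A2"}), on="SNP", how="inner")
    if merged.empty:
        raise ValueError("no SNPs shared with the reference")

    n_not_in_ref = table.n_snps - len(merged)

    ambiguous = [
        (a1, a2) in _AMBIGUOUS_PAIRS
        for a1, a2 in zip(merged["A1"], merged["A2"])
    ]
    ambiguous = np.asarray(ambiguous)

    a1, a2 = merged["A1"], merged["A2"]
    r1, r2 = merged["REF_A1"], merged["REF_A2"]
    c1 = a1.str.translate(_COMPLEMENT)
    c2 = a2.str.translate(_COMPLEMENT)

    same = ((a1 == r1) & (a2 == r2)).to_numpy() | ((c1 == r1) & (c2 == r2)).to_numpy()
    swapped = ((a1 == r2) & (a2 == r1)).to_numpy() | ((c1 == r2) & (c2 == r1)).to_numpy()
    keep = (same | swapped) & ~ambiguous

    out = merged.loc[keep, CANONICAL_COLUMNS].copy()
    flip = swapped[keep] & ~same[keep]
    out.loc[flip, "Z"] = -out.loc[flip, "Z"]
    out.loc[flip, "FREQ"] = 1.0 - out.loc[flip, "FREQ"]
    out[["A1", "A2"]] = merged.loc[keep, ["REF_A1", "REF_A2"]].to_numpy()

    n_ambiguous = int(ambiguous.sum())
    n_mismatch = int((~(same | swapped) & ~ambiguous).sum())
    out = out.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    return table._replace(out,
                          **{"not in reference": n_not_in_ref,
                             "strand-ambiguous": n_ambiguous,
                             "allele mismatch": n_mismatch})


def qc_filter(table: SumstatsTable, info_min: float = 0.9,
              maf_min: float = 0.05) -> SumstatsTable:
    """Retain records with INFO > ``info_min`` and MAF > ``maf_min``.

    Records with missing INFO (typically directly-genotyped panels) pass the
    INFO filter; records with missing FREQ fail the MAF filter only if
    ``maf_min > 0``.
    """
    if not (0 <= info_min <= 1 and 0 <= maf_min <= 0.5):
        raise ValueError("thresholds out of range")
    df = table.df
    info_ok = df["INFO"].isna() | (df["INFO"] > info_min)
    maf = np.minimum(df["FREQ"], 1.0 - df["FREQ"])
    maf_ok = (maf > maf_min).fillna(maf_min <= 0)
    keep = info_ok & maf_ok
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("qc_filter removed every record of %s", table.trait)
    return table._replace(out,
                          **{"low INFO": int((~info_ok).sum()),
                             "low MAF": int((~maf_ok & info_ok).sum())})


def intersect(tables: list[SumstatsTable]) -> list[SumstatsTable]:
    """Restrict every table to the SNP ids shared by all, in identical order."""
    if len(tables) < 2:
        raise ValueError("need at least two tables to intersect")
    shared = set(tables[0].df["SNP"])
    for t in tables[1:]:
        shared &= set(t.df["SNP"])
    if not shared:
        raise ValueError("no shared SNPs across tables")
    out = []
    for t in tables:
        df = t.df[t.df["SNP"].isin(shared)]
        df = df.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
        out.append(t._replace(df, **{"not shared": t.n_snps - len(df)}))
    first = out[0].df["SNP"].to_numpy()
    for t in out[1:]:
        if not np.array_equal(t.df["SNP"].to_numpy(), first):
            # positions disagree across files; fall back to id order of table 0
            order = pd.Index(first)
            t.df = t.df.set_index("SNP").loc[order].reset_index()[CANONICAL_COLUMNS]
    return out


def align_ldscores(tables: list[SumstatsTable], ld: LDScoreTable) -> tuple[list[SumstatsTable], np.ndarray]:
    """Inner-join tables with the LD-score SNPs; returns tables + aligned ℓ vector."""
    ld_map = ld.df.set_index("SNP")["L2"]
    shared = tables[0].df["SNP"][tables[0].df["SNP"].isin(ld_map.index)]
    if shared.empty:
        raise ValueError("no overlap between sumstats and LD scores")
    out = [t._replace(t.df[t.df["SNP"].isin(set(shared))].reset_index(drop=True),
                      **{"no LD score": int((~t.df["SNP"].isin(ld_map.index)).sum())})
           for t in tables]
    ell = ld_map.loc[out[0].df["SNP"]].to_numpy(float)
    return out, ell
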