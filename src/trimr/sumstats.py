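"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

The pipeline's tabular dialect is a tab-separated file with a header row
naming at least ``snp``, ``effect_allele``, ``other_allele``, ``beta``,
``se`` and ``pval``; ``eaf`` and ``n`` are optional.  ``NA`` denotes a
missing value.  Common alias headers from consortium downloads (``rsid``,
``p``, ``b``, ``standard_error`` ...) are canonicalized on read.

Betas for binary traits are interpreted as log-odds, so odds ratios are
``exp(beta)`` throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = {"A", "C", "G", "T"}

#: canonical column order of a summary-statistics table
SUMSTAT_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "eaf", "n"]

MANDATORY_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

#: header aliases seen across GWAS sources, lower-cased
COLUMN_ALIASES = {
    "snp": "snp",
    "rsid": "snp",
    "variant_id": "snp",
    "markername": "snp",
    "effect_allele": "effect_allele",
    "a1": "effect_allele",
    "other_allele": "other_allele",
    "a2": "other_allele",
    "beta": "beta",
    "b": "beta",
    "effect": "beta",
    "se": "se",
    "standard_error": "se",
    "stderr": "se",
    "pval": "pval",
    "p": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "eaf": "eaf",
    "effect_allele_freq": "eaf",
    "freq": "eaf",
    "n": "n",
    "samplesize": "n",
    "sample_size": "n",
}


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def is_valid(self) -> bool:
        return record_mask(pd.DataFrame([self.as_row()])).iloc[0]

    def as_row(self) -> dict:
        return {
            "snp": self.snp_id,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "eaf": self.eaf,
            "n": self.n,
        }


@dataclass
class LDMatrix:
    """Squared pairwise correlations between SNPs, with optional bp positions."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: Optional[dict[str, int]] = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r2.shape} does not match {k} SNP ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("LD r2 entries must lie in [0, 1]")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, a: str, b: str) -> float:
        """r² between two SNPs; unknown SNPs are treated as unlinked (r²=0)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def position(self, snp: str) -> Optional[int]:
        if self.positions is None:
            return None
        return self.positions.get(snp)


def _canonicalize_columns(df: pd.DataFrame, path: str) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in COLUMN_ALIASES:
            renames[col] = COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def record_mask(df: pd.DataFrame) -> pd.Series:
    """Row-wise validity under the record invariants.

    se > 0, pval in (0, 1], finite beta, alleles single ACGT letters that
    differ, eaf (if present) strictly inside (0, 1), n (if present) >= 2.
    """
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    beta = pd.to_numeric(df["beta"], errors="coerce")
    se = pd.to_numeric(df["se"], errors="coerce")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    ok = (
        ea.isin(VALID_ALLELES)
        & oa.isin(VALID_ALLELES)
        & (ea != oa)
        & np.isfinite(beta)
        & (se > 0)
        & (pval > 0)
        & (pval <= 1)
    )
    if "eaf" in df.columns:
        eaf = pd.to_numeric(df["eaf"], errors="coerce")
        ok &= eaf.isna() | ((eaf > 0) & (eaf < 1))
    if "n" in df.columns:
        n = pd.to_numeric(df["n"], errors="coerce")
        ok &= n.isna() | (n >= 2)
    return ok


def clean_sumstats(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    """Canonicalize, validate and deduplicate a summary-statistics frame.

    Invalid rows are dropped with a logged count; duplicate SNP ids keep
    the row with the smallest p-value.
    """
    df = df.copy()
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["snp"] = df["snp"].astype(str)
    for col in ("beta", "se", "pval", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    mask = record_mask(df)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) violating record invariants", source, n_dropped)
    df = df.loc[mask]

    # duplicate snp ids: keep the smallest p-value (stable order otherwise)
    df = df.sort_values(["pval"], kind="stable").drop_duplicates("snp", keep="first")
    df = df.sort_index().reset_index(drop=True)
    return df[SUMSTAT_COLUMNS]


def read_sumstats(path: str | Path, trait_label: str = "") -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV into a canonical frame.

    Returns a DataFrame with columns ``SUMSTAT_COLUMNS``; the trait label is
    stored in ``df.attrs["trait"]``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty summary-statistics file") from None
    if df.empty and len(df.columns) == 0:
        raise ValueError(f"{path}: empty summary-statistics file")
    df = _canonicalize_columns(df, str(path))
    df = clean_sumstats(df, source=str(path))
    df.attrs["trait"] = trait_label or path.stem
    return df


def read_ld(path: str | Path) -> LDMatrix:
    """Read an LD matrix from square TSV (id header) or long TSV (snp_a, snp_b, r2).

    In long format, unlisted pairs default to r² = 0.  Asymmetries beyond
    1e-8 or r² outside [0, 1] are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = [str(c).strip().lower() for c in df.columns]
    if cols[:3] == ["snp_a", "snp_b", "r2"] or set(cols[:3]) == {"snp_a", "snp_b", "r2"}:
        df.columns = cols
        snps = sorted(set(df["snp_a"].astype(str)) | set(df["snp_b"].astype(str)))
        idx = {s: i for i, s in enumerate(snps)}
        mat = np.zeros((len(snps), len(snps)))
        np.fill_diagonal(mat, 1.0)
        for a, b, r2 in zip(df["snp_a"].astype(str), df["snp_b"].astype(str), df["r2"]):
            r2 = float(r2)
            if not 0 <= r2 <= 1:
                raise ValueError(f"{path}: r2 {r2} outside [0, 1] for pair ({a}, {b})")
            ia, ib = idx[a], idx[b]
            for i, j in ((ia, ib), (ib, ia)):
                if i != j and mat[i, j] != 0 and abs(mat[i, j] - r2) > 1e-8:
                    raise ValueError(f"{path}: conflicting r2 for pair ({a}, {b})")
            mat[ia, ib] = mat[ib, ia] = r2 if ia != ib else 1.0
        return LDMatrix(snp_ids=snps, r2=mat)

    # square format: first column holds SNP ids, header names columns
    df = df.set_index(df.columns[0])
    snps = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != snps:
        raise ValueError(f"{path}: square LD matrix header and index disagree")
    mat = df.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{path}: LD matrix asymmetric beyond 1e-8")
    if (mat < 0).any() or (mat > 1).any():
        raise ValueError(f"{path}: r2 entries outside [0, 1]")
    return LDMatrix(snp_ids=snps, r2=mat)


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with >= 6 significant digits on floats."""
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
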