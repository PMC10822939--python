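"""Instrument selection, quality filtering and exposure-outcome harmonization.

The QC chain applied to each exposure before any causal estimate is:

  1. p-value filter (strict ``p < threshold``; 1e-5 for microbiota
     exposures, 5e-8 for disease exposures),
  2. greedy LD clumping (keep the most significant SNP per locus, drop
     neighbours with r² >= 0.001 within a 10,000 kb window),
  3. weak-instrument filter (per-SNP F > 10),
  4. removal of palindromic (A/T, C/G) SNPs,
  5. minor-allele-frequency filter (MAF < 0.01 excluded),
  6. harmonization of exposure and outcome onto a shared effect allele.

Each stage only removes or relabels rows, never invents SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, SUMSTAT_COLUMNS

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class SelectionConfig:
    """Instrument-selection thresholds.

    ``p_threshold`` defaults to the locus-wide microbiota setting 1e-5;
    disease exposures use 5e-8 (see :func:`for_disease_exposure`).
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    maf_min: float = 0.01
    drop_palindromic: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.f_min <= 0:
            raise ValueError("f_min must be > 0")

    @classmethod
    def for_disease_exposure(cls, **overrides) -> "SelectionConfig":
        overrides.setdefault("p_threshold", 5e-8)
        return cls(**overrides)


@dataclass
class InstrumentStrength:
    """Variance explained and F-statistic of an instrument set."""

    r2: float
    n: int
    k: int
    f: float


@dataclass
class HarmonizedSet:
    """Exposure/outcome instrument pairs on a shared effect-allele convention."""

    snp_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def exclude(self, indices) -> "HarmonizedSet":
        """A copy with the given integer indices removed (drop log not carried)."""
        mask = np.ones(len(self), dtype=bool)
        mask[list(indices)] = False
        return HarmonizedSet(
            snp_ids=self.snp_ids[mask], beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask], beta_out=self.beta_out[mask],
            se_out=self.se_out[mask], eaf_exp=self.eaf_exp[mask],
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Back-convert to exposure/outcome summary-statistic frames.

        Alleles are emitted as a fixed non-palindromic pair since the set is
        already on a common convention; p-values recomputed from beta/se.
        """
        from scipy import stats

        def _frame(beta, se):
            pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
            return pd.DataFrame({
                "snp": self.snp_ids, "effect_allele": "A", "other_allele": "G",
                "beta": beta, "se": se, "pval": pval,
                "eaf": self.eaf_exp, "n": np.nan,
            })[SUMSTAT_COLUMNS]

        return _frame(self.beta_exp, self.se_exp), _frame(self.beta_out, self.se_out)


def select_by_p(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Retain SNPs with association p strictly below the threshold."""
    return records.loc[records["pval"] < p_threshold].reset_index(drop=True)


def ld_clump(records: pd.DataFrame, ld: Optional[LDMatrix],
             clump_r2: float = 0.001, window_kb: int = 10_000) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    Keep the most significant remaining SNP, drop every SNP with
    r² >= ``clump_r2`` within ``window_kb`` of it, recurse.  Without
    positions only the r² rule applies; a SNP absent from the LD matrix is
    treated as unlinked with a logged warning.  Equal p-values break ties
    lexicographically on snp id for determinism.
    """
    if records.empty or ld is None:
        if ld is None and not records.empty:
            logger.info("no LD matrix supplied: clumping skipped, all SNPs retained")
        return records.reset_index(drop=True)

    missing = [s for s in records["snp"] if s not in ld]
    if missing:
        logger.warning("%d SNP(s) missing from LD matrix, treated as r2=0", len(missing))

    order = records.sort_values(["pval", "snp"], kind="stable")
    window_bp = window_kb * 1_000
    kept: list[str] = []
    dropped: set[str] = set()
    for snp in order["snp"]:
        if snp in dropped:
            continue
        kept.append(snp)
        pos = ld.position(snp)
        for other in order["snp"]:
            if other == snp or other in dropped or other in kept:
                continue
            r2 = ld.r2_between(snp, other)
            if r2 < clump_r2:
                continue
            opos = ld.position(other)
            if pos is not None and opos is not None and abs(pos - opos) > window_bp:
                continue  # outside the distance window: independent loci
            dropped.add(other)
    keep_mask = records["snp"].isin(kept)
    return records.loc[keep_mask].reset_index(drop=True)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F = R²(n−k−1) / (k(1−R²))."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return r2 * (n - k - 1) / (k * (1 - r2))


def per_snp_r2(beta: float, se: float, n: int) -> float:
    """Variance explained by one SNP via the regression-t identity t²/(t²+n−2)."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 2:
        raise ValueError("n must be > 2")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def f_filter(records: pd.DataFrame, f_min: float = 10.0,
             n_fallback: Optional[int] = None) -> pd.DataFrame:
    """Drop SNPs whose per-SNP F-statistic is not strictly greater than f_min.

    Per-SNP F uses k=1 and the record's own sample size (``n_fallback``
    where n is missing); records with no usable n are retained with a
    warning.
    """
    if records.empty:
        return records.reset_index(drop=True)
    n = records["n"].copy()
    if n_fallback is not None:
        n = n.fillna(n_fallback)
    keep = np.ones(len(records), dtype=bool)
    n_unknown = 0
    for i, (beta, se, ni) in enumerate(zip(records["beta"], records["se"], n)):
        if pd.isna(ni) or ni <= 3:
            n_unknown += 1
            continue
        r2 = per_snp_r2(beta, se, int(ni))
        keep[i] = f_statistic(r2, int(ni), 1) > f_min
    if n_unknown:
        logger.warning("%d SNP(s) lack a sample size; retained without an F check", n_unknown)
    return records.loc[keep].reset_index(drop=True)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return frozenset((effect_allele, other_allele)) in _PALINDROMIC


def drop_palindromic(records: pd.DataFrame) -> pd.DataFrame:
    """Remove A/T and C/G SNPs, whose strand cannot be resolved from alleles."""
    if records.empty:
        return records.reset_index(drop=True)
    pal = records.apply(lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1)
    n_dropped = int(pal.sum())
    if n_dropped:
        logger.info("dropped %d palindromic SNP(s)", n_dropped)
    return records.loc[~pal].reset_index(drop=True)


def maf_filter(records: pd.DataFrame, maf_min: float = 0.01) -> pd.DataFrame:
    """Exclude SNPs whose minor-allele frequency is strictly below maf_min.

    Records without eaf are retained with a warning (frequency unknown).
    """
    if records.empty:
        return records.reset_index(drop=True)
    eaf = records["eaf"]
    maf = np.minimum(eaf, 1 - eaf)
    keep = eaf.isna() | (maf >= maf_min)
    n_noeaf = int(eaf.isna().sum())
    if n_noeaf:
        logger.warning("%d SNP(s) lack eaf; retained without a MAF check", n_noeaf)
    return records.loc[keep].reset_index(drop=True)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_palindromic_snps: bool = True) -> HarmonizedSet:
    """Align outcome records onto each exposure SNP's effect allele.

    Same allele pair, same orientation: kept as-is.  Swapped alleles:
    outcome beta negated (eaf complementing is implicit — only exposure eaf
    is carried).  A strand flip (complementing both outcome alleles) is
    attempted before declaring a mismatch, except for palindromic pairs
    where the flip is indistinguishable.  Exposure-side values are never
    modified.
    """
    out_by_snp = {r.snp: r for r in outcome.itertuples(index=False)}
    rows = []
    dropped: list[tuple[str, str]] = []
    for r in exposure.itertuples(index=False):
        pal = is_palindromic(r.effect_allele, r.other_allele)
        if drop_palindromic_snps and pal:
            dropped.append((r.snp, "palindromic"))
            continue
        o = out_by_snp.get(r.snp)
        if o is None:
            dropped.append((r.snp, "missing_in_outcome"))
            continue
        beta_out = _align_outcome_beta(r.effect_allele, r.other_allele,
                                       o.effect_allele, o.other_allele, o.beta,
                                       allow_strand_flip=not pal)
        if beta_out is None:
            dropped.append((r.snp, "allele_mismatch"))
            continue
        rows.append((r.snp, r.beta, r.se, beta_out, o.se, r.eaf))

    if rows:
        snp, b_exp, se_exp, b_out, se_out, eaf = map(np.array, zip(*rows))
    else:
        snp = np.array([], dtype=object)
        b_exp = se_exp = b_out = se_out = eaf = np.array([], dtype=float)
    return HarmonizedSet(snp_ids=snp, beta_exp=b_exp, se_exp=se_exp,
                         beta_out=b_out, se_out=se_out, eaf_exp=eaf,
                         dropped=dropped)


def _align_outcome_beta(exp_ea: str, exp_oa: str, out_ea: str, out_oa: str,
                        out_beta: float, allow_strand_flip: bool) -> Optional[float]:
    """Outcome beta on the exposure's effect allele, or None if incompatible."""
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return out_beta
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return -out_beta
    if allow_strand_flip:
        flip_ea, flip_oa = _COMPLEMENT[out_ea], _COMPLEMENT[out_oa]
        if (flip_ea, flip_oa) == (exp_ea, exp_oa):
            return out_beta
        if (flip_ea, flip_oa) == (exp_oa, exp_ea):
            return -out_beta
    return None


def filter_named_taxa(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Remove bacterial traits without a specific name (rows named "unknown")."""
    return taxonomy.loc[taxonomy["name"] != "unknown"].reset_index(drop=True)


def qc_chain(exposure: pd.DataFrame, outcome: pd.DataFrame,
             ld: Optional[LDMatrix] = None,
             config: Optional[SelectionConfig] = None,
             n_exposure: Optional[int] = None) -> HarmonizedSet:
    """The full instrument pipeline: p-filter, clump, F-filter, palindromic,
    MAF, harmonize.  Returns the harmonized instrument set."""
    cfg = config or SelectionConfig()
    sel = select_by_p(exposure, cfg.p_threshold)
    sel = ld_clump(sel, ld, cfg.clump_r2, cfg.clump_window_kb)
    sel = f_filter(sel, cfg.f_min, n_fallback=n_exposure)
    if cfg.drop_palindromic:
        sel = drop_palindromic(sel)
    sel = maf_filter(sel, cfg.maf_min)
    return harmonize(sel, outcome, drop_palindromic_snps=cfg.drop_palindromic)
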