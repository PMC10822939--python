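"""Orchestration of exposure-outcome MR grids with association classification.

For every exposure-outcome pair the pipeline runs the instrument QC chain,
the three estimators (IVW with the Q-driven fixed/random choice, MR-Egger,
weighted median), the sensitivity battery (MR-PRESSO, leave-one-out,
Steiger), and classifies the association:

* **nominal** — IVW p < 0.05;
* **stable**  — nominal, and no directional pleiotropy by the Egger
  intercept (p > 0.05), and either a clean MR-PRESSO global test (p > 0.05)
  or a concordant outlier-corrected estimate (distortion p >= 0.05), and
  not dominated by a single SNP in leave-one-out, and a correct Steiger
  direction;
* **strong**  — stable, and IVW p below the per-rank Bonferroni threshold
  0.05/m where m is the number of traits tested at that taxonomic rank.

The classes are nested: strong implies stable implies nominal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .estimators import (EggerResult, HeterogeneityResult, MREstimate,
                         ivw, ivw_both, mr_egger, weighted_median)
from .instruments import HarmonizedSet, SelectionConfig, qc_chain
from .sensitivity import LooResult, PressoResult, SteigerResult, leave_one_out, mr_presso, steiger
from .sumstats import LDMatrix

logger = logging.getLogger(__name__)

CLASS_ORDER = ["none", "nominal", "stable", "strong"]


def bonferroni_threshold(rank: str, m: int) -> float:
    """Per-rank Bonferroni significance threshold 0.05/m for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 0.05 / m


@dataclass
class RankThresholds:
    """Map from taxonomic rank to (number of tests, 0.05/m threshold)."""

    per_rank: dict[str, tuple[int, float]]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "RankThresholds":
        return cls({rank: (m, bonferroni_threshold(rank, m)) for rank, m in counts.items()})

    @classmethod
    def from_taxonomy(cls, taxonomy: pd.DataFrame) -> "RankThresholds":
        counts = taxonomy["rank"].value_counts().to_dict()
        return cls.from_counts({str(k): int(v) for k, v in counts.items()})

    def threshold(self, rank: str) -> float:
        if rank not in self.per_rank:
            return 0.05  # non-taxon legs (disease exposures): single-trait rank
        return self.per_rank[rank][1]


@dataclass
class AssociationRecord:
    """Everything the report prints for one exposure-outcome pair."""

    exposure: str
    outcome: str
    rank: str
    n_snps: int
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    heterogeneity: Optional[HeterogeneityResult] = None
    egger: Optional[EggerResult] = None
    presso: Optional[PressoResult] = None
    loo: Optional[LooResult] = None
    steiger: Optional[SteigerResult] = None
    classification: str = "none"
    reason: str = ""


def classify(record: AssociationRecord, thresholds: RankThresholds,
             nominal_alpha: float = 0.05) -> str:
    """Apply the nested nominal/stable/strong rule to a populated record.

    A record missing its sensitivity block is capped at nominal with a
    warning (robustness cannot be certified).
    """
    primary = record.estimates.get("ivw")
    if primary is None or primary.pval >= nominal_alpha:
        return "none"

    sens_complete = (record.egger is not None and record.presso is not None
                     and record.loo is not None and record.steiger is not None)
    if not sens_complete:
        logger.warning("%s -> %s: sensitivity block incomplete, classification capped at nominal",
                       record.exposure, record.outcome)
        return "nominal"

    egger_clean = record.egger.intercept_pval > 0.05
    presso = record.presso
    presso_clean = presso.global_pval > 0.05 or (
        presso.distortion_pval is not None
        and presso.distortion_pval >= 0.05
        and presso.beta_corrected is not None
        and np.sign(presso.beta_corrected) == np.sign(presso.beta_all)
    )
    loo_clean = not record.loo.dominated
    steiger_ok = record.steiger.correct_direction and not record.steiger.ambiguous

    if not (egger_clean and presso_clean and loo_clean and steiger_ok):
        return "nominal"
    if primary.pval < thresholds.threshold(record.rank):
        return "strong"
    return "stable"


@dataclass
class TraitTable:
    """One trait's summary statistics plus grid metadata."""

    label: str
    data: pd.DataFrame
    rank: str = "disease"
    n: Optional[int] = None


def analyse_pair(exposure: TraitTable, outcome: TraitTable,
                 qc: Optional[SelectionConfig] = None,
                 ld: Optional[LDMatrix] = None,
                 thresholds: Optional[RankThresholds] = None,
                 nominal_alpha: float = 0.05,
                 n_boot: int = 1000, n_sim: int = 1000,
                 seed: int = 0) -> AssociationRecord:
    """QC chain, estimators, sensitivity battery and classification for one pair."""
    thresholds = thresholds or RankThresholds({})
    hs = qc_chain(exposure.data, outcome.data, ld=ld, config=qc, n_exposure=exposure.n)
    rec = AssociationRecord(exposure=exposure.label, outcome=outcome.label,
                            rank=exposure.rank, n_snps=len(hs))
    if len(hs) == 0:
        rec.reason = "no_instruments"
        return rec

    est_auto, het = ivw(hs, model="auto")
    rec.estimates["ivw"] = est_auto
    rec.heterogeneity = het
    if len(hs) >= 2:
        fixed, random_, _ = ivw_both(hs)
        rec.estimates["ivw_fixed"] = fixed
        rec.estimates["ivw_random"] = random_

    if len(hs) >= 3:
        egger, egger_est = mr_egger(hs)
        rec.egger = egger
        rec.estimates["egger"] = egger_est
        rec.estimates["weighted_median"] = weighted_median(hs, n_boot=n_boot, seed=seed)
    if len(hs) >= 4:
        rec.presso = mr_presso(hs, n_sim=n_sim, seed=seed)
    if len(hs) >= 2:
        rec.loo = leave_one_out(hs, nominal_alpha=nominal_alpha)

    n_exp = exposure.n or _median_n(exposure.data)
    n_out = outcome.n or _median_n(outcome.data)
    if n_exp and n_out:
        rec.steiger = steiger(hs, int(n_exp), int(n_out))

    rec.classification = classify(rec, thresholds, nominal_alpha=nominal_alpha)
    return rec


def _median_n(df: pd.DataFrame) -> Optional[int]:
    n = df["n"].dropna()
    return int(n.median()) if len(n) else None


def run_grid(exposures: list[TraitTable], outcomes: list[TraitTable],
             qc: Optional[SelectionConfig] = None,
             ld: Optional[LDMatrix] = None,
             thresholds: Optional[RankThresholds] = None,
             nominal_alpha: float = 0.05,
             n_boot: int = 1000, n_sim: int = 1000,
             seed: int = 0) -> list[AssociationRecord]:
    """Run every exposure x outcome pair; fully deterministic given the seed.

    Per-pair seeds are spawned from the master seed in grid order, so the
    result is a pure function of (inputs, config, seed).
    """
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(len(exposures) * len(outcomes))
    records = []
    i = 0
    for exp in exposures:
        for out in outcomes:
            pair_seed = int(pair_seeds[i].generate_state(1)[0] % (2**31))
            i += 1
            records.append(analyse_pair(exp, out, qc=qc, ld=ld, thresholds=thresholds,
                                        nominal_alpha=nominal_alpha, n_boot=n_boot,
                                        n_sim=n_sim, seed=pair_seed))
    return records


_REPORT_COLUMNS = [
    "exposure", "outcome", "rank", "n_snps",
    "beta_ivw", "se_ivw", "or_ivw", "or_ci_low", "or_ci_high", "pval_ivw", "ivw_model",
    "beta_ivw_fixed", "pval_ivw_fixed", "beta_ivw_random", "pval_ivw_random",
    "beta_egger", "pval_egger", "egger_intercept", "egger_intercept_pval",
    "beta_wmedian", "pval_wmedian",
    "q", "q_pval",
    "presso_global_pval", "presso_n_outliers", "presso_distortion_pval",
    "loo_dominated", "steiger_correct", "steiger_pval",
    "classification", "reason",
]


def report_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Flatten association records into the tabular study report."""
    rows = []
    for r in records:
        ivw_est = r.estimates.get("ivw")
        egger_est = r.estimates.get("egger")
        wm = r.estimates.get("weighted_median")
        fixed = r.estimates.get("ivw_fixed")
        rand = r.estimates.get("ivw_random")
        rows.append({
            "exposure": r.exposure, "outcome": r.outcome, "rank": r.rank,
            "n_snps": r.n_snps,
            "beta_ivw": ivw_est.beta if ivw_est else np.nan,
            "se_ivw": ivw_est.se if ivw_est else np.nan,
            "or_ivw": ivw_est.or_ if ivw_est else np.nan,
            "or_ci_low": ivw_est.or_ci[0] if ivw_est else np.nan,
            "or_ci_high": ivw_est.or_ci[1] if ivw_est else np.nan,
            "pval_ivw": ivw_est.pval if ivw_est else np.nan,
            "ivw_model": ivw_est.method if ivw_est else "",
            "beta_ivw_fixed": fixed.beta if fixed else np.nan,
            "pval_ivw_fixed": fixed.pval if fixed else np.nan,
            "beta_ivw_random": rand.beta if rand else np.nan,
            "pval_ivw_random": rand.pval if rand else np.nan,
            "beta_egger": egger_est.beta if egger_est else np.nan,
            "pval_egger": egger_est.pval if egger_est else np.nan,
            "egger_intercept": r.egger.intercept if r.egger else np.nan,
            "egger_intercept_pval": r.egger.intercept_pval if r.egger else np.nan,
            "beta_wmedian": wm.beta if wm else np.nan,
            "pval_wmedian": wm.pval if wm else np.nan,
            "q": r.heterogeneity.q if r.heterogeneity else np.nan,
            "q_pval": r.heterogeneity.pval if r.heterogeneity else np.nan,
            "presso_global_pval": r.presso.global_pval if r.presso else np.nan,
            "presso_n_outliers": len(r.presso.outliers) if r.presso else np.nan,
            "presso_distortion_pval": (r.presso.distortion_pval
                                       if r.presso and r.presso.distortion_pval is not None
                                       else np.nan),
            "loo_dominated": r.loo.dominated if r.loo else np.nan,
            "steiger_correct": r.steiger.correct_direction if r.steiger else np.nan,
            "steiger_pval": r.steiger.pval if r.steiger else np.nan,
            "classification": r.classification,
            "reason": r.reason,
        })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(records: list[AssociationRecord], path) -> None:
    """Write the study report TSV, one association per row."""
    from .sumstats import write_results

    write_results(report_frame(records), path)
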