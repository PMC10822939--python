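"""Synthetic GWAS summary statistics with known causal ground truth.

The generating model is the standard linear summary-statistics model used
throughout the two-sample MR literature.  For SNP j with true instrument
strength gamma_j > 0, true causal effect theta and pleiotropic direct
effect alpha_j:

    gamma_hat_j = gamma_j + eps_xj,          eps_xj ~ N(0, se_xj^2)
    Gamma_hat_j = theta * gamma_j + alpha_j + eps_yj,   eps_yj ~ N(0, se_yj^2)

with per-SNP standard errors tied to allele frequency and sample size the
way they are in a real GWAS of a standardized trait:

    se ~= 1 / sqrt(2 * maf_j * (1 - maf_j) * n)

so F-statistics respond to sample size.  Direct effects come in three
flavours: balanced (alpha_j ~ N(0, pleio_tau^2)), directional (mean
pleio_mu != 0), and InSIDE-violating (alpha_j correlated with gamma_j via
inside_rho).  A configurable fraction of SNPs is made a gross outlier with
|alpha_j| at least ten times the balanced-pleiotropy scale.

Every draw is governed by the config seed; identical configs give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats import SUMSTAT_COLUMNS, LDMatrix

TAXONOMIC_RANKS = ["phylum", "class", "order", "family", "genus"]


@dataclass
class SimConfig:
    """Generating parameters for one exposure-outcome pair.

    Defaults emulate the microbiota-exposure setting: an exposure GWAS of
    18,340 participants (the MiBioGen meta-analysis size) and a disease
    outcome GWAS of 65,642 (the IBD consortium case+control total), with
    instrument strengths giving per-SNP F well above the weak-instrument
    cutoff of 10.
    """

    n_snps: int = 150
    n_exp: int = 18_340
    n_out: int = 65_642
    theta: float = 0.0
    gamma_mean: float = 0.1
    gamma_sd: float = 0.04
    pleio_tau: float = 0.0
    pleio_mu: float = 0.0
    inside_rho: float = 0.0
    outlier_frac: float = 0.0
    maf_low: float = 0.1
    maf_high: float = 0.5
    ld_blocks: Optional[Sequence[tuple[int, float]]] = None
    seed: int = 0
    #: separate stream for the outcome-side noise: pairs sharing `seed` but
    #: differing here share the exposure GWAS (instruments, alleles, maf)
    #: while their outcomes stay independent
    outcome_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_exp < 100 or self.n_out < 100:
            raise ValueError("sample sizes must be >= 100")
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")
        if self.pleio_tau < 0:
            raise ValueError("pleio_tau must be >= 0")
        if not 0.01 <= self.maf_low < self.maf_high <= 0.5:
            raise ValueError("maf range must satisfy 0.01 <= low < high <= 0.5")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier_indices: frozenset[int]
    seed: int


# non-palindromic allele pairs only: harmonization scrambling is tested
# separately, the generator itself emits strand-unambiguous SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def simulate_pair(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw exposure and outcome summary statistics with known truth.

    Returns (exposure, outcome, truth); both frames use the canonical
    summary-statistics columns and share snp ids, alleles and eaf.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps

    maf = rng.uniform(config.maf_low, config.maf_high, size=k)
    # truncated-normal instrument strengths, all positive
    gamma = np.abs(rng.normal(config.gamma_mean, config.gamma_sd, size=k))
    gamma = np.maximum(gamma, 1e-6)

    alpha = np.zeros(k)
    if config.pleio_tau > 0 or config.pleio_mu != 0:
        alpha = rng.normal(config.pleio_mu, config.pleio_tau, size=k)
    if config.inside_rho != 0:
        scale = config.pleio_tau if config.pleio_tau > 0 else 0.01
        alpha = alpha + config.inside_rho * (gamma - gamma.mean()) * scale / max(gamma.std(), 1e-12)

    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exp)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_out)

    n_outliers = int(round(config.outlier_frac * k))
    outlier_idx: frozenset[int] = frozenset()
    if n_outliers:
        idx = rng.choice(k, size=n_outliers, replace=False)
        base = config.pleio_tau
        if base == 0:
            base = abs(config.theta) * float(gamma.mean())
        if base == 0:
            base = float(np.median(se_y))
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
        alpha[idx] = signs * base * rng.uniform(10.0, 15.0, size=n_outliers)
        outlier_idx = frozenset(int(i) for i in idx)

    gamma_hat = gamma + rng.normal(0.0, se_x)
    out_rng = rng if config.outcome_seed is None else np.random.default_rng(config.outcome_seed)
    big_gamma_hat = config.theta * gamma + alpha + out_rng.normal(0.0, se_y)

    from scipy import stats

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snp = np.array([f"rs{j + 1:06d}" for j in range(k)])

    def _frame(beta: np.ndarray, se: np.ndarray, n: int) -> pd.DataFrame:
        pval = 2 * stats.norm.sf(np.abs(beta / se))
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        return pd.DataFrame({
            "snp": snp,
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "se": se,
            "pval": pval,
            "eaf": maf,
            "n": n,
        })[SUMSTAT_COLUMNS]

    exposure = _frame(gamma_hat, se_x, config.n_exp)
    outcome = _frame(big_gamma_hat, se_y, config.n_out)
    truth = SimTruth(theta=config.theta, gamma=gamma, alpha=alpha,
                     outlier_indices=outlier_idx, seed=config.seed)
    return exposure, outcome, truth


def simulate_ld_block(n_snps: int, r2: float, seed: int = 0,
                      snp_ids: Optional[Sequence[str]] = None,
                      start_pos: int = 1_000_000, spacing: int = 1_000) -> LDMatrix:
    """An LD block with constant off-diagonal r² and evenly spaced positions."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must be in [0, 1]")
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:06d}" for j in range(n_snps)]
    else:
        snp_ids = list(snp_ids)
        if len(snp_ids) != n_snps:
            raise ValueError("snp_ids length must equal n_snps")
    mat = np.full((n_snps, n_snps), float(r2))
    np.fill_diagonal(mat, 1.0)
    positions = {s: start_pos + j * spacing for j, s in enumerate(snp_ids)}
    return LDMatrix(snp_ids=snp_ids, r2=mat, positions=positions)


_GENUS_STEMS = ["Bacteroides", "Odoribacter", "Ruminococcus", "Bilophila", "Dorea",
                "Coprococcus", "Barnesiella", "Holdemanella", "Anaerotruncus",
                "Adlercreutzia", "Butyrivibrio", "Subdoligranulum", "Lactobacillus"]


def make_taxonomy_fixture(n_taxa: int = 211, n_unknown: int = 15, seed: int = 0) -> pd.DataFrame:
    """A rank-labelled bacterial taxonomy table with a set number of unnamed taxa.

    Emulates a microbiome GWAS trait list: taxa spread over the five ranks
    phylum/class/order/family/genus, with ``n_unknown`` of them carrying the
    name "unknown" (traits without a specific family or genus name, which
    the instrument-selection stage removes).
    """
    if n_unknown > n_taxa:
        raise ValueError("n_unknown cannot exceed n_taxa")
    rng = np.random.default_rng(seed)
    # genus-heavy rank mix as in real taxon panels
    rank_weights = np.array([0.045, 0.08, 0.095, 0.17, 0.61])
    ranks = rng.choice(TAXONOMIC_RANKS, size=n_taxa, p=rank_weights)
    names = []
    for i, rank in enumerate(ranks):
        stem = _GENUS_STEMS[i % len(_GENUS_STEMS)]
        names.append(f"{rank} {stem}{i + 1}")
    unknown_idx = rng.choice(n_taxa, size=n_unknown, replace=False)
    names = np.array(names, dtype=object)
    names[unknown_idx] = "unknown"
    # unnamed traits only arise at family/genus level
    ranks = np.array(ranks, dtype=object)
    ranks[unknown_idx] = rng.choice(["family", "genus"], size=n_unknown)
    return pd.DataFrame({
        "taxon_id": [f"taxon{i + 1:04d}" for i in range(n_taxa)],
        "rank": ranks,
        "name": names,
    })


def simulate_triangle(
    a: float, b: float, direct: float,
    n_snps_exp: int = 120, n_snps_med: int = 120,
    n: int = 50_000, seed: int = 0, **kwargs,
) -> dict:
    """Simulate an exposure -> mediator -> outcome system.

    True effects: exposure->mediator ``a``, mediator->outcome ``b``,
    exposure->outcome direct effect ``direct``; the total exposure->outcome
    effect is ``direct + a*b``.  Returns the three summary-statistic pairs
    needed for the three MR legs, keyed ``exp_med``, ``med_out``,
    ``exp_out``, plus ``truth`` with the generating effects.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    total = direct + a * b

    cfg1 = SimConfig(n_snps=n_snps_exp, n_exp=n, n_out=n, theta=a, seed=seeds[0], **kwargs)
    exp1, med1, truth1 = simulate_pair(cfg1)
    # same exposure instruments drive the total leg: Gamma = total * gamma
    cfg_total = SimConfig(n_snps=n_snps_exp, n_exp=n, n_out=n, theta=total, seed=seeds[0], **kwargs)
    _, out_total, _ = simulate_pair(cfg_total)

    cfg2 = SimConfig(n_snps=n_snps_med, n_exp=n, n_out=n, theta=b, seed=seeds[1], **kwargs)
    med2, out2, truth2 = simulate_pair(cfg2)

    return {
        "exp_med": (exp1, med1),
        "med_out": (med2, out2),
        "exp_out": (exp1, out_total),
        "truth": {"a": a, "b": b, "direct": direct, "total": total,
                  "mediated": a * b, "seeds": seeds},
    }
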