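"""Pleiotropy and robustness diagnostics for a harmonized instrument set.

Three screens guard each causal estimate:

* **MR-PRESSO** — a parametric simulation test on the residual sum of
  squares (RSS) of the SNP-outcome effects around their leave-one-out IVW
  predictions.  The global test asks whether the observed RSS is larger
  than expected under a no-pleiotropy model; the outlier test localizes
  offending SNPs by comparing each SNP's squared residual to its simulated
  distribution (Bonferroni across SNPs); the distortion test asks whether
  removing the outliers changes the estimate more than removing random
  SNP subsets of the same size would.
* **Leave-one-out** — refits the (auto-model) IVW excluding each SNP in
  turn and flags associations whose nominal significance or sign hinges on
  a single instrument.
* **Steiger directionality** — compares the instrument variance explained
  on the exposure and outcome sides (Fisher-z test on the implied
  correlations) to confirm the assumed causal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .estimators import ivw, wald_ratios
from .instruments import HarmonizedSet, per_snp_r2


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: np.ndarray
    outliers: list[int]
    distortion_pval: Optional[float]
    beta_all: float
    beta_corrected: Optional[float]
    n_sim: int
    seed: int


@dataclass
class LooResult:
    snp_ids: np.ndarray
    beta_without: np.ndarray
    pval_without: np.ndarray
    dominated: bool
    dominating_snps: list[str] = field(default_factory=list)


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    ambiguous: bool
    z: float
    pval: float


def _loo_ivw_slopes(gamma: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each SNP, in closed form.

    The IVW estimate is the weighted through-origin regression slope
    sum(w*g*G)/sum(w*g*g) with outcome-variance weights; dropping SNP j
    subtracts its contribution from both sums.
    """
    num = np.sum(w * gamma * G)
    den = np.sum(w * gamma**2)
    return (num - w * gamma * G) / (den - w * gamma**2)


def mr_presso(hs: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0, n_distortion: int = 1000) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    Observed RSS uses leave-one-out expected outcome effects: SNP j's
    prediction is gamma_hat_j times the IVW slope fitted without j, with
    residuals weighted by 1/se_out².  The null distribution re-simulates
    both sides (exposure effects around their estimates, outcome effects
    around the leave-one-out predictions) ``n_sim`` times and recomputes
    the same statistic, so global_pval = (1 + #{sim RSS >= obs})/(n_sim+1).
    Per-SNP outlier p-values use each SNP's simulated weighted-residual
    distribution and are Bonferroni-compared to ``outlier_alpha``.  When
    outliers are found, the distortion test compares the pre/post-removal
    IVW difference to removals of ``n_distortion`` random subsets of the
    same size.
    """
    k = len(hs)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 SNPs")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)

    gamma, G = hs.beta_exp, hs.beta_out
    se_x, se_y = hs.se_exp, hs.se_out
    w = 1.0 / se_y**2

    beta_loo = _loo_ivw_slopes(gamma, G, w)
    resid = G - gamma * beta_loo
    wres_obs = w * resid**2
    rss_obs = float(np.sum(wres_obs))

    # parametric null: no pleiotropy, expected outcome effect gamma*beta(-j)
    g_sim = rng.normal(gamma, se_x, size=(n_sim, k))
    G_sim = rng.normal(gamma * beta_loo, se_y, size=(n_sim, k))
    num = np.sum(w * g_sim * G_sim, axis=1, keepdims=True)
    den = np.sum(w * g_sim**2, axis=1, keepdims=True)
    beta_loo_sim = (num - w * g_sim * G_sim) / (den - w * g_sim**2)
    wres_sim = w * (G_sim - g_sim * beta_loo_sim) ** 2
    rss_sim = wres_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_pvals = (1 + np.sum(wres_sim >= wres_obs, axis=0)) / (n_sim + 1)
    outliers = [int(i) for i in np.flatnonzero(outlier_pvals < outlier_alpha / k)]

    est_all, _ = ivw(hs, model="auto")
    beta_corrected = None
    distortion_pval = None
    if outliers and len(outliers) < k - 1:
        corrected = ivw(hs.exclude(outliers), model="auto")[0]
        beta_corrected = corrected.beta
        d_obs = beta_corrected - est_all.beta
        n_out = len(outliers)
        d_null = np.empty(n_distortion)
        for b in range(n_distortion):
            subset = rng.choice(k, size=n_out, replace=False)
            d_null[b] = ivw(hs.exclude(subset), model="auto")[0].beta - est_all.beta
        distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_distortion + 1))

    return PressoResult(global_rss=rss_obs, global_pval=global_pval,
                        outlier_pvals=np.asarray(outlier_pvals), outliers=outliers,
                        distortion_pval=distortion_pval, beta_all=est_all.beta,
                        beta_corrected=beta_corrected, n_sim=n_sim, seed=seed)


def leave_one_out(hs: HarmonizedSet, nominal_alpha: float = 0.05) -> LooResult:
    """Auto-model IVW excluding each SNP in turn; flags single-SNP domination.

    ``dominated`` is true iff the all-SNP result is nominally significant
    and excluding some single SNP either lifts its p-value above
    ``nominal_alpha`` or flips the estimate's sign.
    """
    k = len(hs)
    if k < 2:
        raise ValueError("leave-one-out requires at least 2 SNPs")
    est_all, _ = ivw(hs, model="auto")
    betas = np.empty(k)
    pvals = np.empty(k)
    for j in range(k):
        est_j, _ = ivw(hs.exclude([j]), model="auto")
        betas[j] = est_j.beta
        pvals[j] = est_j.pval
    dominating: list[str] = []
    if est_all.pval < nominal_alpha:
        for j in range(k):
            if pvals[j] >= nominal_alpha or np.sign(betas[j]) != np.sign(est_all.beta):
                dominating.append(str(hs.snp_ids[j]))
    return LooResult(snp_ids=hs.snp_ids.copy(), beta_without=betas,
                     pval_without=pvals, dominated=bool(dominating),
                     dominating_snps=dominating)


def steiger(hs: HarmonizedSet, n_exp: int, n_out: int) -> SteigerResult:
    """Directionality test: does the instrument explain more exposure than outcome?

    Per-SNP variance explained is t²/(t²+n−2) on each side, summed over the
    instrument set; the two implied correlations sqrt(r²) are compared with
    a Fisher-z two-sample test.
    """
    if len(hs) == 0:
        raise ValueError("Steiger test requires at least 1 SNP")
    r2_exp = float(sum(per_snp_r2(b, s, n_exp) for b, s in zip(hs.beta_exp, hs.se_exp)))
    r2_out = float(sum(per_snp_r2(b, s, n_out) for b, s in zip(hs.beta_out, hs.se_out)))
    r2_exp = min(r2_exp, 1 - 1e-12)
    r2_out = min(r2_out, 1 - 1e-12)
    z_num = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    z_den = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = float(z_num / z_den)
    pval = float(min(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    return SteigerResult(r2_exposure=r2_exp, r2_outcome=r2_out,
                         correct_direction=r2_exp > r2_out,
                         ambiguous=r2_exp == r2_out, z=z, pval=pval)
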