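"""Causal-effect estimators over harmonized instrument sets.

Per-SNP Wald ratios are meta-analysed by inverse-variance weighting (IVW);
Cochran's Q decides between the fixed- and random-effects models
(random when Q's p < 0.05, via multiplicative overdispersion of the SE).
MR-Egger regression adds a free intercept that absorbs average directional
pleiotropy, and the weighted median is consistent when at least half the
instrument weight is on valid instruments.

All estimators work on the first-order Wald-ratio approximation: the
ratio SE is se_out/|beta_exp|, ignoring exposure-side uncertainty (the
convention of standard two-sample MR tooling); a second-order SE is
available behind a flag on :func:`wald_ratio`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import HarmonizedSet


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (beta) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    model_note: str = ""

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test across per-SNP Wald ratios."""

    q: float
    df: int
    pval: float

    @property
    def defined(self) -> bool:
        return self.df >= 1


@dataclass
class EggerResult:
    """MR-Egger regression: slope (causal estimate) and pleiotropy intercept."""

    slope: float
    slope_se: float
    slope_pval: float
    intercept: float
    intercept_se: float
    intercept_pval: float
    n_snps: int


_Z95 = float(stats.norm.ppf(0.975))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with its delta-method SE."""
    if beta_exp == 0:
        raise ValueError("undefined ratio: exposure beta is zero")
    ratio = beta_out / beta_exp
    var = se_out**2 / beta_exp**2
    if second_order:
        var += beta_out**2 * se_exp**2 / beta_exp**4
    return ratio, float(np.sqrt(var))


def wald_ratios(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP ratios and first-order SEs for a harmonized set."""
    if np.any(hs.beta_exp == 0):
        raise ValueError("undefined ratio: exposure beta is zero for some SNP")
    ratios = hs.beta_out / hs.beta_exp
    ses = hs.se_out / np.abs(hs.beta_exp)
    return ratios, ses


def cochran_q(ratios: np.ndarray, ratio_ses: np.ndarray,
              pooled_beta: float) -> HeterogeneityResult:
    """Q = sum of inverse-variance-weighted squared deviations from the pool."""
    ratios = np.asarray(ratios, dtype=float)
    ratio_ses = np.asarray(ratio_ses, dtype=float)
    k = len(ratios)
    if k < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    w = 1.0 / ratio_ses**2
    q = float(np.sum(w * (ratios - pooled_beta) ** 2))
    df = k - 1
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, pval=pval)


def _mk_estimate(method: str, beta: float, se: float, n_snps: int,
                 note: str = "", df: Optional[int] = None) -> MREstimate:
    if df is None:
        pval = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        crit = _Z95
    else:
        pval = 2 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
        crit = float(stats.t.ppf(0.975, df))
    pval = float(min(max(pval, np.finfo(float).tiny), 1.0))
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - crit * se), ci_high=float(beta + crit * se),
                      pval=pval, n_snps=n_snps, model_note=note)


def ivw(hs: HarmonizedSet, model: str = "auto",
        het_alpha: float = 0.05) -> tuple[MREstimate, Optional[HeterogeneityResult]]:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``model``: ``fixed`` (SE = 1/sqrt(sum of weights)), ``random``
    (multiplicative overdispersion, SE scaled by sqrt(max(1, Q/df))), or
    ``auto`` — random when the Q test is significant at ``het_alpha``,
    fixed otherwise.  With a single SNP the estimate is the Wald ratio and
    Q is undefined (returned as None).
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(hs)
    if k == 0:
        raise ValueError("IVW requires at least one SNP")
    ratios, ses = wald_ratios(hs)
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))

    if k == 1:
        est = _mk_estimate("wald", beta, se_fixed, 1, note="single SNP: Wald ratio, Q undefined")
        return est, None

    het = cochran_q(ratios, ses, beta)
    overdispersion = float(np.sqrt(max(1.0, het.q / het.df)))
    if model == "auto":
        chosen = "random" if het.pval < het_alpha else "fixed"
    else:
        chosen = model
    se = se_fixed * overdispersion if chosen == "random" else se_fixed
    est = _mk_estimate(f"ivw_{chosen}", beta, se, k,
                       note=f"Q={het.q:.4g} (df={het.df}, p={het.pval:.3g})")
    return est, het


def ivw_both(hs: HarmonizedSet) -> tuple[MREstimate, MREstimate, Optional[HeterogeneityResult]]:
    """Fixed- and random-effects IVW side by side (they share the point estimate)."""
    fixed, het = ivw(hs, model="fixed")
    random_, _ = ivw(hs, model="random")
    return fixed, random_, het


def mr_egger(hs: HarmonizedSet) -> tuple[EggerResult, MREstimate]:
    """MR-Egger: WLS of outcome betas on exposure betas with a free intercept.

    Exposure effects are oriented non-negative first (flipping the sign of
    both betas for SNPs with a negative exposure effect), weights are
    1/se_out²; slope and intercept are tested on a t-reference with k−2 df.
    """
    k = len(hs)
    if k < 3:
        raise ValueError("insufficient instruments for Egger (need >= 3)")
    sign = np.where(hs.beta_exp < 0, -1.0, 1.0)
    x = hs.beta_exp * sign
    y = hs.beta_out * sign
    w = 1.0 / hs.se_out**2

    sw = np.sum(w)
    swx = np.sum(w * x)
    swy = np.sum(w * y)
    swxx = np.sum(w * x * x)
    swxy = np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate design: exposure betas have no spread")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = y - intercept - slope * x
    df = k - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    var_slope = sigma2 * sw / det
    var_inter = sigma2 * swxx / det
    slope_se = float(np.sqrt(var_slope))
    inter_se = float(np.sqrt(var_inter))

    def _tp(b, s):
        return float(min(max(2 * stats.t.sf(abs(b) / s, df) if s > 0 else 1.0,
                             np.finfo(float).tiny), 1.0))

    egger = EggerResult(slope=float(slope), slope_se=slope_se, slope_pval=_tp(slope, slope_se),
                        intercept=float(intercept), intercept_se=inter_se,
                        intercept_pval=_tp(intercept, inter_se), n_snps=k)
    est = _mk_estimate("egger", slope, slope_se, k, df=df,
                       note=f"intercept={intercept:.4g} (p={egger.intercept_pval:.3g})")
    return egger, est


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Bowden-style weighted median of the Wald ratios with bootstrap SE.

    Ratios are sorted ascending; the estimate interpolates where the
    standardized cumulative weight crosses one half.  The SE comes from
    ``n_boot`` parametric bootstrap resamples (normal around each observed
    ratio with its ratio SE), seeded for reproducibility.
    """
    k = len(hs)
    if k < 3:
        raise ValueError("weighted median requires >= 3 SNPs")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ratios, ses = wald_ratios(hs)
    w = 1.0 / ses**2
    beta = _weighted_median_point(ratios, w)

    rng = np.random.default_rng(seed)
    boot = rng.normal(ratios, ses, size=(n_boot, k))
    boot_est = _weighted_median_rows(boot, w)
    se = float(boot_est.std(ddof=1))
    return _mk_estimate("weighted_median", beta, se, k,
                        note=f"bootstrap SE over {n_boot} resamples")


def _weighted_median_rows(ratio_rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for a (B, k) matrix of bootstrap ratios."""
    order = np.argsort(ratio_rows, axis=1, kind="stable")
    r = np.take_along_axis(ratio_rows, order, axis=1)
    w = weights[order]
    cw = np.cumsum(w, axis=1)
    p = (cw - 0.5 * w) / cw[:, -1:]
    # p is strictly increasing in each row (weights > 0)
    idx = (p < 0.5).sum(axis=1)
    out = np.empty(len(r))
    lo = idx == 0
    hi = idx == r.shape[1]
    out[lo] = r[lo, 0]
    out[hi] = r[hi, -1]
    mid = ~(lo | hi)
    i = idx[mid]
    rows = np.flatnonzero(mid)
    p0, p1 = p[rows, i - 1], p[rows, i]
    r0, r1 = r[rows, i - 1], r[rows, i]
    out[mid] = r0 + (0.5 - p0) / (p1 - p0) * (r1 - r0)
    return out


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weights p_j = (cum − w_j/2)/total."""
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))
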