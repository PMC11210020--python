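"""Univariable two-sample MR estimators and heterogeneity diagnostics.

All estimators consume a :class:`~summr.sumstats.HarmonizedSet` with a single
exposure. Standard errors for IVW use a multiplicative random-effects model:
the fixed-effect SE is inflated by max(1, sqrt(Q/df)) so underdispersion never
shrinks it. P-values are two-sided normal; CIs are Wald at z = 1.959964.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._stats import Z95, two_sided_p
from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)


class EstimatorError(ValueError):
    """Degenerate inputs (zero exposure effects, too few instruments, ...)."""


@dataclass
class MREstimate:
    """A causal-effect estimate with Wald uncertainty and heterogeneity stats."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    i2: float | None = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int,
                     q_stat: float | None = None, i2: float | None = None) -> "MREstimate":
        return cls(method, float(beta), float(se),
                   float(beta - Z95 * se), float(beta + Z95 * se),
                   float(two_sided_p(beta, se)), int(n_snps), q_stat, i2)


@dataclass
class EggerResult:
    """MR-Egger slope plus the intercept pleiotropy test and the I²_GX
    regression-dilution diagnostic."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    i2_gx: float


def _single(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if hset.n_exposures != 1:
        raise EstimatorError("univariable estimator needs a single exposure; use mvmr")
    return (np.asarray(hset.bx, float), np.asarray(hset.sex, float),
            np.asarray(hset.by, float), np.asarray(hset.sey, float))


def wald_ratio(bx: float, sex: float, by: float, sey: float,
               second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate by/bx.

    First-order SE is sey/|bx|; ``second_order`` adds the exposure-noise term
    sqrt(sey²/bx² + by²·sex²/bx⁴).
    """
    if bx == 0:
        raise EstimatorError("degenerate instrument: bx == 0")
    beta = by / bx
    if second_order:
        se = float(np.sqrt(sey**2 / bx**2 + by**2 * sex**2 / bx**4))
    else:
        se = sey / abs(bx)
    return MREstimate.from_beta_se("wald", beta, se, 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sey: np.ndarray,
              ) -> tuple[float, float, float, int]:
    """(beta, fixed-effect se, Q, df) for weighted through-origin regression."""
    w = 1.0 / sey**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise EstimatorError("degenerate set: all bx zero")
    beta = float(np.sum(w * bx * by)) / denom
    se0 = denom ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se0, q, len(bx) - 1


def ivw_mre(hset: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted (1/sey²) through-origin regression of by on bx; the fixed-effect
    SE is scaled by max(1, sqrt(Q/(L−1))). A single-SNP set falls back to the
    Wald ratio.
    """
    bx, sex, by, sey = _single(hset)
    if len(bx) == 1:
        logger.info("ivw_mre on single SNP: falling back to Wald ratio")
        return wald_ratio(bx[0], sex[0], by[0], sey[0])
    beta, se0, q, df = _ivw_core(bx, by, sey)
    se = se0 * max(1.0, np.sqrt(q / df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    est = MREstimate.from_beta_se("ivw_mre", beta, se, len(bx), q, i2)
    return est


def cochran_q(hset: HarmonizedSet, beta: float) -> tuple[float, int, float]:
    """Cochran's Q of per-SNP residuals around a fitted slope, df and I² (%)."""
    bx, _, by, sey = _single(hset)
    if len(bx) < 2:
        raise EstimatorError("need at least 2 instruments for Q")
    q = float(np.sum((by - beta * bx) ** 2 / sey**2))
    df = len(bx) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2


def egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of by on bx with an intercept.

    Each SNP is oriented so bx ≥ 0 before fitting (sign flips applied to the
    (bx, by) pair). Slope and intercept SEs carry the multiplicative
    random-effects scaling with df = L−2. I²_GX quantifies dilution of the
    slope by exposure-measurement noise.
    """
    bx, sex, by, sey = _single(hset)
    L = len(bx)
    if L < 3:
        raise EstimatorError("MR-Egger needs at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sey**2
    X = np.column_stack([np.ones(L), bx])
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.matrix_rank(xtwx) < 2 or np.isclose(np.ptp(bx), 0.0):
        raise EstimatorError("insufficient variation in bx for Egger regression")
    cov0 = np.linalg.inv(xtwx)
    coef = cov0 @ (X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (L - 2)))
    se = np.sqrt(np.diag(cov0)) * scale
    i2 = max(0.0, (q - (L - 2)) / q) * 100.0 if q > 0 else 0.0
    slope = MREstimate.from_beta_se("egger_slope", coef[1], se[1], L, q, i2)
    # regression-dilution diagnostic on the instrument-strength axis
    wx = 1.0 / sex**2
    bbar = float(np.sum(wx * bx) / np.sum(wx))
    q_gx = float(np.sum(wx * (bx - bbar) ** 2))
    i2_gx = max(0.0, (q_gx - (L - 1)) / q_gx) if q_gx > 0 else 0.0
    return EggerResult(slope, float(coef[0]), float(se[0]),
                       float(two_sided_p(coef[0], se[0])), i2_gx)


def _wm_point(bx: np.ndarray, by: np.ndarray, sey: np.ndarray) -> float:
    r = by / bx
    w = bx**2 / sey**2
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimate: the inverse-variance-weighted 50% quantile of
    the per-SNP Wald ratios, consistent when ≥50% of the weight is valid.

    SE is the SD of the estimator over ``n_boot`` parametric-bootstrap
    replicates resampling bx ~ N(bx, sex) and by ~ N(by, sey).
    """
    bx, sex, by, sey = _single(hset)
    if len(bx) < 3:
        raise EstimatorError("weighted median needs at least 3 instruments")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = _wm_point(bx, by, sey)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sex, size=(n_boot, len(bx)))
    bys = rng.normal(by, sey, size=(n_boot, len(bx)))
    boots = np.array([_wm_point(bxs[i], bys[i], sey) for i in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", est, se, len(bx))


def subset_estimates(hset: HarmonizedSet, classes: Mapping[str, str] | np.ndarray,
                     ) -> dict[str, MREstimate]:
    """IVW within each instrument class; single-SNP classes fall back to the
    Wald ratio. ``classes`` maps variant_id → label (or per-SNP label array)."""
    if isinstance(classes, Mapping):
        labels = np.array([classes[v] for v in hset.variant_id], dtype=object)
    else:
        labels = np.asarray(classes, dtype=object)
        if len(labels) != hset.n_snps:
            raise ValueError("one label per SNP required")
    out: dict[str, MREstimate] = {}
    for label in sorted(set(labels)):
        sub = hset.subset(labels == label)
        est = ivw_mre(sub)
        est.method = f"subset[{label}]" if sub.n_snps > 1 else f"subset[{label}]:wald"
        out[label] = est
    return out
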