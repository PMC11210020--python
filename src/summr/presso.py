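"""MR-PRESSO: simulation-based global heterogeneity test, per-SNP outlier
test with Bonferroni correction, and distortion test with outlier-corrected
re-estimation.

The observed statistic is the leave-one-out weighted residual sum of squares:
RSS = Σ_j w_j (by_j − θ_{−j}·bx_j)² with θ_{−j} the IVW slope fitted without
SNP j and w_j = 1/sey_j². Null datasets are drawn parametrically
(by*_j ~ N(θ_{−j}·bx_j, sey_j), bx*_j ~ N(bx_j, sex_j)) and scored the same
way; empirical p-values use the add-one rule so they are never zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimatorError, MREstimate, ivw_mre
from .sumstats import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    per_snp_p: np.ndarray  # Bonferroni-adjusted, clipped at 1
    outliers: list[str]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int | None
    raw: MREstimate = field(default=None)  # type: ignore[assignment]


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized; works on (..., L) stacks."""
    num = w * bx * by
    den = w * bx**2
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def _loo_residuals(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    theta = _loo_slopes(bx, by, w)
    return w * (by - theta * bx) ** 2


def presso(hset: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
           seed: int | None = None) -> PressoResult:
    """Run the three MR-PRESSO tests and re-estimate without flagged outliers.

    Deterministic given (hset, n_sim, seed).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if hset.n_exposures != 1:
        raise EstimatorError("presso requires a single exposure")
    bx, sex = np.asarray(hset.bx, float), np.asarray(hset.sex, float)
    by, sey = np.asarray(hset.by, float), np.asarray(hset.sey, float)
    L = len(bx)
    if L < 4:
        raise EstimatorError("MR-PRESSO needs at least 4 instruments")
    w = 1.0 / sey**2
    rng = np.random.default_rng(seed)

    obs_resid = _loo_residuals(bx, by, w)
    rss_obs = float(obs_resid.sum())

    # parametric null: expected by under each SNP's leave-one-out slope
    theta_loo = _loo_slopes(bx, by, w)
    by_sim = rng.normal(theta_loo * bx, sey, size=(n_sim, L))
    bx_sim = rng.normal(bx, sex, size=(n_sim, L))
    sim_resid = _loo_residuals(bx_sim, by_sim, w)
    rss_sim = sim_resid.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_raw = (1 + np.sum(sim_resid >= obs_resid, axis=0)) / (n_sim + 1)
    per_snp_p = np.minimum(1.0, per_snp_raw * L)
    flagged = per_snp_p < outlier_alpha
    outliers = [str(v) for v in np.asarray(hset.variant_id)[flagged]]

    raw = ivw_mre(hset)
    corrected: MREstimate | None
    distortion_p: float | None
    if not flagged.any():
        corrected, distortion_p = raw, None
    elif flagged.all():
        raise EstimatorError("MR-PRESSO flagged every instrument")
    else:
        corrected = ivw_mre(hset.subset(~flagged))
        k = int(flagged.sum())
        if corrected.beta == 0:
            distortion_p = None
        else:
            d_obs = (raw.beta - corrected.beta) / corrected.beta
            # null: distortion from removing k SNPs at random
            scores = rng.random((n_sim, L))
            keep_masks = np.argsort(scores, axis=1) >= k  # drop k per draw
            num = (w * bx * by)[None, :] * keep_masks
            den = (w * bx**2)[None, :] * keep_masks
            theta_rand = num.sum(axis=1) / den.sum(axis=1)
            d_null = (raw.beta - theta_rand) / theta_rand
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(rss_obs, global_p, per_snp_p, outliers, corrected,
                        distortion_p, n_sim, seed, raw=raw)
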