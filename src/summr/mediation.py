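"""Multivariable MR and the two-step mediation decomposition.

The indirect effect is the product of the exposure→mediator estimate (step 1)
and the mediator→outcome estimate conditional on the exposure (step 2, from
MVMR); its SE comes from the delta method. The per-doubling helper rescales
log-odds-of-liability effects by ln 2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import LN2, Z95, two_sided_p
from .estimators import EstimatorError, MREstimate, ivw_mre
from .sumstats import HarmonizedSet


@dataclass
class MvmrResult:
    """Conditional per-exposure effects from a joint weighted fit."""

    estimates: dict[str, MREstimate]
    n_snps: int
    q_stat: float
    i2: float


@dataclass
class ValueCI:
    value: float
    se: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_value_se(cls, value: float, se: float) -> "ValueCI":
        return cls(float(value), float(se), float(value - Z95 * se), float(value + Z95 * se))


@dataclass
class MediationResult:
    total: MREstimate
    direct: MREstimate
    step1: MREstimate
    step2: MREstimate
    indirect: ValueCI
    proportion_mediated: ValueCI


class MediationError(ValueError):
    pass


def mvmr(hset: HarmonizedSet) -> MvmrResult:
    """Weighted through-origin multiple regression of by on the K exposure-beta
    columns (weights 1/sey²); SEs carry multiplicative scaling max(1, √(Q/(L−K))).
    """
    bx = np.asarray(hset.bx, float)
    if bx.ndim == 1:
        est = ivw_mre(hset)
        return MvmrResult({hset.exposure_names[0]: est}, hset.n_snps,
                          est.q_stat if est.q_stat is not None else 0.0,
                          est.i2 if est.i2 is not None else 0.0)
    by, sey = np.asarray(hset.by, float), np.asarray(hset.sey, float)
    L, K = bx.shape
    if L < K + 1:
        raise EstimatorError(f"MVMR with {K} exposures needs at least {K + 1} SNPs")
    w = 1.0 / sey**2
    xtwx = bx.T @ (w[:, None] * bx)
    rank = np.linalg.matrix_rank(xtwx)
    if rank < K:
        raise EstimatorError(
            f"collinear exposure betas (rank {rank} < {K}): {hset.exposure_names}")
    cov0 = np.linalg.inv(xtwx)
    coef = cov0 @ (bx.T @ (w * by))
    q = float(np.sum(w * (by - bx @ coef) ** 2))
    df = L - K
    scale = max(1.0, np.sqrt(q / df))
    ses = np.sqrt(np.diag(cov0)) * scale
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    estimates = {
        name: MREstimate.from_beta_se(f"mvmr[{name}]", coef[k], ses[k], L, q, i2)
        for k, name in enumerate(hset.exposure_names)}
    return MvmrResult(estimates, L, q, i2)


def mediate(step1: MREstimate, step2: MREstimate, total: MREstimate,
            direct: MREstimate | None = None, cov_ab: float = 0.0,
            second_order: bool = False, log_scale_ci: bool = False) -> MediationResult:
    """Product-of-coefficients mediation with delta-method uncertainty.

    indirect = a·b with a = step1.beta, b = step2.beta and
    se² = a²·se_b² + b²·se_a² (+ se_a²·se_b² when ``second_order``,
    + 2ab·cov_ab when step estimates covary). The proportion mediated is
    indirect/total with delta variance (se_ind/T)² + (ind·se_T/T²)².
    ``log_scale_ci`` reports the proportion CI on the log scale instead.
    """
    a, sa = step1.beta, step1.se
    b, sb = step2.beta, step2.se
    t, st = total.beta, total.se
    if t == 0:
        raise MediationError("total effect is zero: proportion mediated undefined")
    ind = a * b
    var_ind = a**2 * sb**2 + b**2 * sa**2 + 2 * a * b * cov_ab
    if second_order:
        var_ind += sa**2 * sb**2
    se_ind = float(np.sqrt(var_ind))
    prop = ind / t
    se_prop = float(np.sqrt((se_ind / t) ** 2 + (ind * st / t**2) ** 2))
    prop_ci = ValueCI.from_value_se(prop, se_prop)
    if log_scale_ci:
        if prop <= 0 or ind == 0:
            raise MediationError("log-scale CI requires a positive proportion")
        se_log = np.sqrt((se_ind / ind) ** 2 + (st / t) ** 2)
        prop_ci = ValueCI(prop, se_prop,
                          float(prop * np.exp(-Z95 * se_log)),
                          float(prop * np.exp(Z95 * se_log)))
    if direct is None:
        direct = MREstimate.from_beta_se("direct(total-indirect)", t - ind,
                                         float(np.sqrt(st**2 + se_ind**2)), total.n_snps)
    return MediationResult(total, direct, step1, step2,
                           ValueCI.from_value_se(ind, se_ind), prop_ci)


def per_doubling(beta: float, se: float = 0.0) -> tuple[float, float]:
    """Rescale a per-log-odds-of-liability effect (and SE) to per doubling of
    exposure prevalence: multiply by ln 2 ≈ 0.693."""
    return beta * LN2, se * LN2


def per_doubling_estimate(est: MREstimate) -> MREstimate:
    """Apply :func:`per_doubling` to a full estimate; CI endpoints transform
    consistently and the p-value is unchanged up to the identical z."""
    beta, se = per_doubling(est.beta, est.se)
    out = MREstimate.from_beta_se(est.method + ":per-doubling", beta, se,
                                  est.n_snps, est.q_stat, est.i2)
    return out
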