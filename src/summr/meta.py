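"""Random-effects meta-analysis, instrument strength, and power.

Meta-analysis is DerSimonian–Laird; power follows the standard normal
approximation for a two-sided Wald test of an instrumented effect.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from ._stats import Z95, two_sided_p
from .estimators import MREstimate
from .sumstats import GwasTable


@dataclass
class MetaEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    tau2: float
    i2_meta: float
    cohort_estimates: list[tuple[str, float, float]]

    def as_mr_estimate(self, method: str = "meta_random", n_snps: int = 0) -> MREstimate:
        return MREstimate(method, self.beta, self.se, self.ci_low, self.ci_high,
                          self.pval, n_snps)


@dataclass
class InstrumentStrength:
    r2_total: float
    f_stat: float
    n: float
    k: int
    weak_instrument_unlikely: bool  # F > 10
    se_fallback_used: bool = False


@dataclass
class PowerSpec:
    alpha: float = 0.05
    n: float = 0
    r2: float = 0.0
    case_fraction: float | None = None
    effect: float | None = None  # beta, or log(OR) for binary outcomes
    power: float | None = None


class PowerError(ValueError):
    pass


def meta_random(estimates: list[tuple[str, float, float]]) -> MetaEstimate:
    """DerSimonian–Laird random-effects pooling of (label, beta, se) rows.

    tau² = max(0, (Q − (m−1)) / (Σw − Σw²/Σw)) with fixed-effect weights
    w = 1/se²; the pooled estimate uses weights 1/(se² + tau²). A single
    cohort passes through unchanged.
    """
    if not estimates:
        raise ValueError("no cohort estimates supplied")
    labels = [e[0] for e in estimates]
    b = np.array([e[1] for e in estimates], dtype=float)
    se = np.array([e[2] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("cohort SEs must be positive")
    m = len(b)
    if m == 1:
        return MetaEstimate(float(b[0]), float(se[0]), float(b[0] - Z95 * se[0]),
                            float(b[0] + Z95 * se[0]), float(two_sided_p(b[0], se[0])),
                            0.0, 0.0, list(zip(labels, b, se)))
    w = 1.0 / se**2
    b_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (m - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * b) / np.sum(w_re))
    se_p = float(np.sum(w_re) ** -0.5)
    i2 = max(0.0, (q - (m - 1)) / q) * 100.0 if q > 0 else 0.0
    return MetaEstimate(pooled, se_p, pooled - Z95 * se_p, pooled + Z95 * se_p,
                        float(two_sided_p(pooled, se_p)), tau2, i2,
                        list(zip(labels, b, se)))


def instrument_strength(table: GwasTable, n: float | None = None) -> InstrumentStrength:
    """Variance explained and approximate F-statistic of an instrument set.

    For a standardized trait each SNP contributes r²_j = 2·eaf_j(1−eaf_j)·β_j²;
    when eaf is missing the sample-size fallback r²_j = β_j²/(β_j² + n·se_j²)
    is used (flagged). F = r²·(n−k−1)/((1−r²)·k).
    """
    df = table.df
    k = len(df)
    if k == 0:
        raise ValueError("empty instrument table")
    if n is None:
        n_col = df["n"].dropna()
        if n_col.empty:
            raise ValueError("sample size unavailable: pass n explicitly")
        n = float(n_col.max())
    beta = df["beta"].to_numpy(dtype=float)
    eaf = df["eaf"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    have_eaf = np.isfinite(eaf)
    r2_j = np.where(have_eaf, 2.0 * eaf * (1.0 - eaf) * beta**2,
                    beta**2 / (beta**2 + n * se**2))
    fallback = bool((~have_eaf).any())
    r2 = float(np.sum(r2_j))
    if r2 >= 1:
        raise ValueError(f"r2_total = {r2:.3f} >= 1: trait not on a standardized scale?")
    f = r2 * (n - k - 1) / ((1 - r2) * k) if r2 > 0 else 0.0
    return InstrumentStrength(r2, float(f), n, k, f > 10, fallback)


def _validate_power(spec: PowerSpec, binary: bool) -> None:
    if not 0 < spec.alpha < 1:
        raise PowerError("alpha must be in (0,1)")
    if not 0 < spec.r2 < 1:
        raise PowerError("r2 must be in (0,1)")
    if spec.n <= 0:
        raise PowerError("n must be positive")
    if binary:
        if spec.case_fraction is None or not 0 < spec.case_fraction < 1:
            raise PowerError("binary outcome requires case_fraction in (0,1)")


def mr_power(spec: PowerSpec, outcome_type: str = "continuous") -> PowerSpec:
    """Power of the two-sided Wald test for an instrumented effect.

    continuous: power = Φ(|b|·√(n·r²) − z₁₋α/₂);
    binary:     power = Φ(|log OR|·√(n·r²·cf·(1−cf)) − z₁₋α/₂).
    At effect 0 this returns the one-tail rejection α/2 (documented convention).
    """
    binary = outcome_type == "binary"
    if outcome_type not in ("continuous", "binary"):
        raise PowerError(f"unknown outcome_type {outcome_type!r}")
    _validate_power(spec, binary)
    if spec.effect is None:
        raise PowerError("effect must be set to compute power")
    z_a = -special.ndtri(spec.alpha / 2.0)
    lam = _ncp_scale(spec, binary)
    power = float(special.ndtr(abs(spec.effect) * lam - z_a))
    return replace(spec, power=power)


def _ncp_scale(spec: PowerSpec, binary: bool) -> float:
    if binary:
        cf = spec.case_fraction
        return float(np.sqrt(spec.n * spec.r2 * cf * (1.0 - cf)))
    return float(np.sqrt(spec.n * spec.r2))


def detectable_effect(spec: PowerSpec, outcome_type: str = "continuous",
                      target_power: float = 0.80) -> float:
    """Smallest |effect| (beta, or log OR for binary) detectable at
    ``target_power``; the inverse of :func:`mr_power`."""
    binary = outcome_type == "binary"
    _validate_power(spec, binary)
    if not 0 < target_power < 1:
        raise PowerError("target_power must be in (0,1)")
    z_a = -special.ndtri(spec.alpha / 2.0)
    z_b = special.ndtri(target_power)
    return float((z_a + z_b) / _ncp_scale(spec, binary))
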