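"""Synthetic GWAS summary statistics under a known structural model.

The generative model: L unlinked instruments with effect-allele frequencies
eaf_j; true per-SNP exposure effects γ_j; a mediator with κ_j = a·γ_j + δ_j
(δ only for a configurable fraction of SNPs, so the mediator has its own
signal and MVMR is identified); an outcome on the log-odds scale with
Γ_j = θ_direct·γ_j + b·κ_j + α_j where α_j is optional horizontal pleiotropy.
Observed betas add per-cohort Normal(0, se_j) noise with
se_j = 1/sqrt(2·eaf_j·(1−eaf_j)·n). Everything is reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import two_sided_p
from .sumstats import GwasTable

PALINDROMIC_CHOICES = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
NONPALINDROMIC_CHOICES = (("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
                          ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"))


@dataclass
class PleiotropyConfig:
    mode: str = "none"  # none | balanced | directional | inside_violation
    mean: float = 0.0
    sd: float = 0.0
    fraction_affected: float = 0.0


@dataclass
class SimulationConfig:
    L: int = 50
    n_exp: float = 200_000
    n_med: float = 200_000
    n_out: float = 200_000
    eaf_range: tuple[float, float] = (0.1, 0.9)
    gamma_sd: float = 0.05
    theta_direct: float = 0.0
    a: float = 0.0
    b: float = 0.0
    delta_sd: float = 0.05
    mediator_fraction: float = 0.5
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    n_cohorts: int = 1
    palindromic_fraction: float = 0.2
    flip_fraction: float = 0.3
    ensure_significant: bool = True
    noise_scale: float = 1.0  # scales sampling noise only; reported SEs unchanged
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L < 4:
            raise ValueError("L must be >= 4")
        if not 0 <= self.pleiotropy.fraction_affected <= 1:
            raise ValueError("fraction_affected must be in [0,1]")
        for name in ("gamma_sd", "delta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("eaf_range must lie strictly inside (0,1)")


@dataclass
class TruthRecord:
    theta_direct: float
    a: float
    b: float
    gamma: np.ndarray  # per-SNP exposure effects
    kappa: np.ndarray  # per-SNP mediator effects
    Gamma: np.ndarray  # per-SNP outcome effects
    alpha: np.ndarray  # pleiotropic offsets
    eaf: np.ndarray
    outlier_ids: list[str] = field(default_factory=list)

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.a * self.b

    @property
    def proportion_mediated_true(self) -> float:
        return self.a * self.b / self.theta_total


@dataclass
class SimResult:
    exposure: GwasTable
    mediator: GwasTable
    outcome_cohorts: list[GwasTable]
    truth: TruthRecord


def _se_vec(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _make_table(name: str, unit: str, vid: np.ndarray, ea: np.ndarray, oa: np.ndarray,
                eaf: np.ndarray, beta: np.ndarray, se: np.ndarray, n: float,
                flip: np.ndarray | None = None) -> GwasTable:
    ea, oa, eaf, beta = ea.copy(), oa.copy(), eaf.copy(), beta.copy()
    if flip is not None and flip.any():
        ea[flip], oa[flip] = oa[flip], ea[flip].copy()
        eaf[flip] = 1.0 - eaf[flip]
        beta[flip] = -beta[flip]
    df = pd.DataFrame({
        "variant_id": vid, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pval": two_sided_p(beta, se), "n": n,
    })
    return GwasTable(name, unit, df)


def simulate(config: SimulationConfig) -> SimResult:
    """Draw exposure, mediator, and per-cohort outcome summary statistics plus
    the ground truth of the generating model."""
    rng = np.random.default_rng(config.seed)
    L = config.L
    vid = np.array([f"rs{i:06d}" for i in range(1, L + 1)], dtype=object)
    eaf = rng.uniform(*config.eaf_range, size=L)
    se_exp = _se_vec(eaf, config.n_exp)

    gamma = rng.normal(0.0, config.gamma_sd, size=L)
    if config.ensure_significant and config.gamma_sd > 0:
        # redraw until each SNP would clear P < 5e-8 even after sampling noise
        zmin = 7.5
        for _ in range(1000):
            weak = np.abs(gamma) / se_exp < zmin
            if not weak.any():
                break
            gamma[weak] = rng.normal(0.0, config.gamma_sd, size=int(weak.sum()))
        else:
            gamma = np.sign(gamma) * np.maximum(np.abs(gamma), zmin * se_exp)

    delta = np.zeros(L)
    n_med_specific = int(round(config.mediator_fraction * L))
    if n_med_specific and config.delta_sd > 0:
        idx = rng.choice(L, size=n_med_specific, replace=False)
        delta[idx] = rng.normal(0.0, config.delta_sd, size=n_med_specific)
    kappa = config.a * gamma + delta

    alpha = np.zeros(L)
    pl = config.pleiotropy
    if pl.mode != "none" and pl.fraction_affected > 0:
        n_aff = int(round(pl.fraction_affected * L))
        idx = rng.choice(L, size=n_aff, replace=False)
        if pl.mode == "balanced":
            alpha[idx] = rng.normal(0.0, pl.sd, size=n_aff)
        elif pl.mode == "directional":
            alpha[idx] = rng.normal(pl.mean, pl.sd, size=n_aff)
        elif pl.mode == "inside_violation":
            # pleiotropy correlated with instrument strength (violates InSIDE)
            alpha[idx] = pl.mean + pl.sd * gamma[idx] / max(config.gamma_sd, 1e-12)
        else:
            raise ValueError(f"unknown pleiotropy mode {pl.mode!r}")
    Gamma = config.theta_direct * gamma + config.b * kappa + alpha

    n_pal = int(round(config.palindromic_fraction * L))
    pal_idx = rng.choice(L, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    pal_mask = np.zeros(L, dtype=bool)
    pal_mask[pal_idx] = True
    ea = np.empty(L, dtype=object)
    oa = np.empty(L, dtype=object)
    pal_pick = rng.integers(0, len(PALINDROMIC_CHOICES), size=L)
    non_pick = rng.integers(0, len(NONPALINDROMIC_CHOICES), size=L)
    for j in range(L):
        ea[j], oa[j] = (PALINDROMIC_CHOICES[pal_pick[j]] if pal_mask[j]
                        else NONPALINDROMIC_CHOICES[non_pick[j]])

    bx_obs = gamma + config.noise_scale * rng.normal(0.0, se_exp)
    exposure = _make_table("exposure", "SD", vid, ea, oa, eaf, bx_obs, se_exp, config.n_exp)

    se_med = _se_vec(eaf, config.n_med)
    bm_obs = kappa + config.noise_scale * rng.normal(0.0, se_med)
    flip_m = rng.random(L) < config.flip_fraction
    mediator = _make_table("mediator", "SD", vid, ea, oa, eaf, bm_obs, se_med,
                           config.n_med, flip=flip_m & ~pal_mask)

    cohorts = []
    se_out = _se_vec(eaf, config.n_out)
    for c in range(config.n_cohorts):
        by_obs = Gamma + config.noise_scale * rng.normal(0.0, se_out)
        flip_o = rng.random(L) < config.flip_fraction
        name = "outcome" if config.n_cohorts == 1 else f"outcome_cohort{c + 1}"
        cohorts.append(_make_table(name, "log-odds", vid, ea, oa, eaf, by_obs,
                                   se_out, config.n_out, flip=flip_o & ~pal_mask))

    truth = TruthRecord(config.theta_direct, config.a, config.b,
                        gamma, kappa, Gamma, alpha, eaf)
    return SimResult(exposure, mediator, cohorts, truth)


def inject_outliers(tables: Sequence[GwasTable], truth: TruthRecord, count: int,
                    offset_multiplier: float, seed: int | None = None,
                    ) -> tuple[list[GwasTable], TruthRecord]:
    """Add ``offset_multiplier``·se_j to ``count`` randomly chosen SNPs' outcome
    betas in every table; refuses to break the majority-valid assumption."""
    if count == 0:
        return list(tables), truth
    L = len(truth.gamma)
    if count >= L / 2:
        raise ValueError(f"count={count} would corrupt >= half of {L} instruments")
    rng = np.random.default_rng(seed)
    first = tables[0].df
    idx = rng.choice(len(first), size=count, replace=False)
    ids = set(first["variant_id"].iloc[idx])
    out_tables = []
    for t in tables:
        df = t.df.copy()
        sel = df["variant_id"].isin(ids)
        # offset applied in each row's own orientation-independent magnitude
        df.loc[sel, "beta"] = df.loc[sel, "beta"] + offset_multiplier * df.loc[sel, "se"]
        df.loc[sel, "pval"] = two_sided_p(df.loc[sel, "beta"].to_numpy(),
                                          df.loc[sel, "se"].to_numpy())
        out_tables.append(t.with_df(df))
    new_truth = replace(truth, outlier_ids=sorted(ids))
    return out_tables, new_truth
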