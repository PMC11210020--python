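"""Orchestration of the full two-step analysis from a single config.

Order per exposure–outcome pair and cohort: instrument selection → blocklist
→ harmonization → IVW (MRE) → sensitivity methods → per-cohort results pooled
by random-effects meta-analysis → per-doubling rescaling for liability
exposures → MVMR + mediation for each configured (exposure, mediator,
outcome) triple. Every number in the report comes from a module operation;
this layer only formats.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import estimators, mediation, meta
from .presso import presso as run_presso
from .estimators import EstimatorError, MREstimate
from .sumstats import (DEFAULT_BLOCKLIST, DEFAULT_EAF_WINDOW, GwasTable, HarmonizedSet,
                       exclude_blocklist, fill_missing_se, harmonize, read_sumstats,
                       select_instruments)

logger = logging.getLogger(__name__)


@dataclass
class TraitSpec:
    name: str
    path: str
    unit: str = "SD"
    column_map: dict[str, str] | None = None


@dataclass
class OutcomeSpec:
    name: str
    unit: str = "log-odds"
    cohorts: dict[str, str] = field(default_factory=dict)  # label -> path


@dataclass
class AnalysisConfig:
    exposures: list[TraitSpec]
    outcomes: list[OutcomeSpec]
    mediators: list[TraitSpec] = field(default_factory=list)
    mediation_triples: list[tuple[str, str, str]] = field(default_factory=list)
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    ld_path: str | None = None
    eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW
    blocklist: list[str] = field(default_factory=lambda: sorted(DEFAULT_BLOCKLIST))
    methods: list[str] = field(default_factory=lambda: ["ivw", "egger", "wm", "presso"])
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    out_dir: str = "mr_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        exposures = [TraitSpec(**t) for t in raw.get("exposures", [])]
        mediators = [TraitSpec(**t) for t in raw.get("mediators", [])]
        outcomes = [OutcomeSpec(**t) for t in raw.get("outcomes", [])]
        triples = [tuple(t) for t in raw.get("mediation_triples", [])]
        kwargs = {k: v for k, v in raw.items()
                  if k not in ("exposures", "mediators", "outcomes", "mediation_triples")}
        if "eaf_window" in kwargs:
            kwargs["eaf_window"] = tuple(kwargs["eaf_window"])
        names = {t.name for t in exposures} | {t.name for t in mediators}
        if len(names) != len(exposures) + len(mediators):
            raise ValueError("exposure/mediator names must not overlap")
        return cls(exposures=exposures, mediators=mediators, outcomes=outcomes,
                   mediation_triples=triples, **kwargs)


@dataclass
class AnalysisReport:
    estimates: pd.DataFrame  # cohort-level and meta rows, tidy
    instruments: pd.DataFrame
    mediation: list[dict[str, Any]]
    presso: list[dict[str, Any]]
    failures: list[dict[str, str]]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False,
                              float_format="%.6g")
        self.instruments.to_csv(out / "instruments.tsv", sep="\t", index=False,
                                float_format="%.6g")
        (out / "mediation.json").write_text(json.dumps(self.mediation, indent=2))
        (out / "presso.json").write_text(json.dumps(self.presso, indent=2))
        (out / "failures.json").write_text(json.dumps(self.failures, indent=2))


def _est_row(est: MREstimate, **extra: Any) -> dict[str, Any]:
    row = {"method": est.method, "beta": est.beta, "se": est.se,
           "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
           "n_snps": est.n_snps, "q": est.q_stat, "i2": est.i2,
           "or": float(np.exp(est.beta)) if abs(est.beta) < 50 else None}
    row.update(extra)
    return row


def _maybe_per_doubling(est: MREstimate, exposure_unit: str) -> MREstimate:
    if exposure_unit == "log-odds":
        return mediation.per_doubling_estimate(est)
    return est


def _prepare_instruments(spec: TraitSpec, cfg: AnalysisConfig,
                         ld: pd.DataFrame | None) -> GwasTable:
    table = read_sumstats(spec.path, column_map=spec.column_map,
                          trait_name=spec.name, trait_unit=spec.unit)
    table = fill_missing_se(table)
    table = select_instruments(table, cfg.p_threshold, ld, cfg.r2_threshold)
    return exclude_blocklist(table, cfg.blocklist)


def leave_one_out(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP-removed IVW estimates; the max-|Δbeta| SNP is flagged."""
    if hset.n_snps < 3:
        raise EstimatorError("leave-one-out needs at least 3 instruments")
    full = estimators.ivw_mre(hset)
    rows = []
    for j in range(hset.n_snps):
        mask = np.ones(hset.n_snps, dtype=bool)
        mask[j] = False
        est = estimators.ivw_mre(hset.subset(mask))
        rows.append({"excluded": str(hset.variant_id[j]), "beta": est.beta,
                     "se": est.se, "delta_beta": est.beta - full.beta})
    df = pd.DataFrame(rows)
    df["max_influence"] = np.abs(df["delta_beta"]) == np.abs(df["delta_beta"]).max()
    return df


def _run_methods(hset: HarmonizedSet, cfg: AnalysisConfig, rows: list[dict],
                 presso_reports: list[dict], context: dict[str, Any]) -> MREstimate:
    unit = context["exposure_unit"]
    ivw = _maybe_per_doubling(estimators.ivw_mre(hset), unit)
    rows.append(_est_row(ivw, **context))
    if "egger" in cfg.methods and hset.n_snps >= 3:
        eg = estimators.egger(hset)
        slope = _maybe_per_doubling(eg.slope, unit)
        rows.append(_est_row(slope, intercept=eg.intercept, intercept_se=eg.intercept_se,
                             intercept_p=eg.intercept_pval, i2_gx=eg.i2_gx, **context))
    if "wm" in cfg.methods and hset.n_snps >= 3:
        wm = estimators.weighted_median(hset, n_boot=cfg.n_boot, seed=cfg.seed)
        rows.append(_est_row(_maybe_per_doubling(wm, unit), **context))
    if "presso" in cfg.methods and hset.n_snps >= 4:
        pr = run_presso(hset, n_sim=cfg.n_sim, seed=cfg.seed)
        corrected = _maybe_per_doubling(pr.corrected, unit)
        corrected.method = "presso_corrected" + (":per-doubling" if unit == "log-odds" else "")
        rows.append(_est_row(corrected, **context))
        presso_reports.append({
            **{k: v for k, v in context.items() if k in ("exposure", "outcome", "cohort")},
            "rss_obs": pr.rss_obs, "global_p": pr.global_p,
            "outliers": pr.outliers, "distortion_p": pr.distortion_p,
            "n_sim": pr.n_sim})
    return ivw


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute the configured analysis; per-pair errors are collected, not fatal."""
    ld = None
    if config.ld_path:
        ld = pd.read_csv(config.ld_path, sep="\t", index_col=0)
    rows: list[dict] = []
    inst_rows: list[dict] = []
    presso_reports: list[dict] = []
    mediation_reports: list[dict] = []
    failures: list[dict[str, str]] = []

    traits: dict[str, TraitSpec] = {t.name: t for t in config.exposures + config.mediators}
    instruments: dict[str, GwasTable] = {}
    for name, spec in traits.items():
        try:
            instruments[name] = _prepare_instruments(spec, config, ld)
            strength = meta.instrument_strength(instruments[name])
            inst_rows.append({"trait": name, "n_snps": strength.k,
                              "r2": strength.r2_total, "f_stat": strength.f_stat,
                              "weak_instrument_unlikely": strength.weak_instrument_unlikely})
        except Exception as exc:  # noqa: BLE001 - per-trait isolation is the contract
            failures.append({"stage": "instruments", "trait": name, "error": str(exc)})

    outcome_tables: dict[tuple[str, str], GwasTable] = {}
    for ospec in config.outcomes:
        for label, path in ospec.cohorts.items():
            try:
                t = read_sumstats(path, trait_name=ospec.name, trait_unit=ospec.unit)
                outcome_tables[(ospec.name, label)] = fill_missing_se(t)
            except Exception as exc:  # noqa: BLE001
                failures.append({"stage": "read-outcome", "trait": f"{ospec.name}/{label}",
                                 "error": str(exc)})

    hsets: dict[tuple[str, str, str], HarmonizedSet] = {}
    for exp_name, exp_table in instruments.items():
        exp_unit = traits[exp_name].unit
        for ospec in config.outcomes:
            cohort_ivw: list[tuple[str, float, float]] = []
            for label in ospec.cohorts:
                key = (ospec.name, label)
                if key not in outcome_tables:
                    continue
                ctx = {"exposure": exp_name, "outcome": ospec.name, "cohort": label,
                       "exposure_unit": exp_unit}
                try:
                    hset = harmonize(exp_table, outcome_tables[key], config.eaf_window)
                    hsets[(exp_name, ospec.name, label)] = hset
                    ivw = _run_methods(hset, config, rows, presso_reports, ctx)
                    cohort_ivw.append((label, ivw.beta, ivw.se))
                except Exception as exc:  # noqa: BLE001
                    failures.append({"stage": "pair", "trait": f"{exp_name}->{ospec.name}/{label}",
                                     "error": str(exc)})
            if cohort_ivw:
                pooled = meta.meta_random(cohort_ivw)
                rows.append(_est_row(
                    pooled.as_mr_estimate("meta_ivw" + (":per-doubling" if exp_unit == "log-odds" else "")),
                    exposure=exp_name, outcome=ospec.name, cohort="meta",
                    exposure_unit=exp_unit, tau2=pooled.tau2, i2_meta=pooled.i2_meta))

    for exp_name, med_name, out_name in config.mediation_triples:
        try:
            report = _mediate_triple(exp_name, med_name, out_name, instruments,
                                     outcome_tables, config, traits)
            mediation_reports.append(report)
        except Exception as exc:  # noqa: BLE001
            failures.append({"stage": "mediation",
                             "trait": f"{exp_name}->{med_name}->{out_name}",
                             "error": str(exc)})

    est_df = pd.DataFrame(rows)
    if not est_df.empty:
        lead = ["exposure", "outcome", "cohort", "method"]
        est_df = est_df[lead + [c for c in est_df.columns if c not in lead]]
        est_df = est_df.sort_values(lead, kind="mergesort").reset_index(drop=True)
    return AnalysisReport(est_df, pd.DataFrame(inst_rows), mediation_reports,
                          presso_reports, failures)


def _mediate_triple(exp_name: str, med_name: str, out_name: str,
                    instruments: dict[str, GwasTable],
                    outcome_tables: dict[tuple[str, str], GwasTable],
                    config: AnalysisConfig, traits: dict[str, TraitSpec]) -> dict:
    exp_inst = instruments[exp_name]
    med_inst = instruments[med_name]
    # step 1: exposure -> mediator, univariable on the exposure's instruments
    med_full = fill_missing_se(read_sumstats(traits[med_name].path,
                                             column_map=traits[med_name].column_map,
                                             trait_name=med_name,
                                             trait_unit=traits[med_name].unit))
    step1 = estimators.ivw_mre(harmonize(exp_inst, med_full, config.eaf_window))

    # union of both traits' instruments drives the MVMR fit
    union_ids = sorted(set(exp_inst.df["variant_id"]) | set(med_inst.df["variant_id"]))
    exp_full = fill_missing_se(read_sumstats(traits[exp_name].path,
                                             column_map=traits[exp_name].column_map,
                                             trait_name=exp_name,
                                             trait_unit=traits[exp_name].unit))
    exp_union = exp_full.with_df(exp_full.df[exp_full.df["variant_id"].isin(union_ids)])
    med_union = med_full.with_df(med_full.df[med_full.df["variant_id"].isin(union_ids)])

    cohort_total: list[tuple[str, float, float]] = []
    cohort_direct: list[tuple[str, float, float]] = []
    cohort_step2: list[tuple[str, float, float]] = []
    cohorts = [(lbl, t) for (oname, lbl), t in outcome_tables.items() if oname == out_name]
    n_snps_uni = n_snps_mv = 0
    for label, otable in cohorts:
        uni = estimators.ivw_mre(harmonize(exp_inst, otable, config.eaf_window))
        mv = mediation.mvmr(harmonize([exp_union, med_union], otable, config.eaf_window))
        cohort_total.append((label, uni.beta, uni.se))
        cohort_direct.append((label, mv.estimates[exp_name].beta, mv.estimates[exp_name].se))
        cohort_step2.append((label, mv.estimates[med_name].beta, mv.estimates[med_name].se))
        n_snps_uni, n_snps_mv = uni.n_snps, mv.n_snps
    total = meta.meta_random(cohort_total).as_mr_estimate("total", n_snps_uni)
    direct = meta.meta_random(cohort_direct).as_mr_estimate("direct_mvmr", n_snps_mv)
    step2 = meta.meta_random(cohort_step2).as_mr_estimate("step2_mvmr", n_snps_mv)
    res = mediation.mediate(step1, step2, total, direct=direct)
    return {
        "exposure": exp_name, "mediator": med_name, "outcome": out_name,
        "total": _est_row(res.total), "direct": _est_row(res.direct),
        "step1": _est_row(res.step1), "step2": _est_row(res.step2),
        "indirect": {"beta": res.indirect.value, "se": res.indirect.se,
                     "ci_low": res.indirect.ci_low, "ci_high": res.indirect.ci_high},
        "proportion_mediated": {"value": res.proportion_mediated.value,
                                "se": res.proportion_mediated.se,
                                "ci_low": res.proportion_mediated.ci_low,
                                "ci_high": res.proportion_mediated.ci_high},
    }
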