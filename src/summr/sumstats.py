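"""Read, validate, filter, and harmonize GWAS summary-statistics tables.

The unit of currency is :class:`GwasTable` (one trait's per-variant summary
statistics) and :class:`HarmonizedSet` (allele-aligned exposure/outcome betas
ready for the estimators).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._stats import two_sided_p, z_from_p

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: HFE-hemochromatosis variants excluded by default from iron-related instruments.
DEFAULT_BLOCKLIST = frozenset({"rs1800562", "rs1799945"})
DEFAULT_EAF_WINDOW = (0.42, 0.58)

#: Header dialects accepted without an explicit column map.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "id", "markername", "variant"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1", "alt"),
    "other_allele": ("other_allele", "oa", "a2", "allele2", "ref", "nea"),
    "eaf": ("eaf", "frq", "freq", "af", "effect_allele_frequency", "maf"),
    "beta": ("beta", "b", "effect", "es"),
    "se": ("se", "stderr", "standard_error"),
    "pval": ("pval", "p", "p_value", "pvalue", "p-value"),
    "n": ("n", "samplesize", "n_total", "sample_size"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
}

MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta")


class SumstatsError(ValueError):
    """Base error for summary-statistics handling."""


class FormatError(SumstatsError):
    """Input file is missing a mandatory column or is malformed."""


class EmptyInputError(SumstatsError):
    """No usable rows remain after validation/filtering."""


class HarmonizationError(SumstatsError):
    """No variant survives harmonization."""


class IncompleteLDError(SumstatsError):
    """The supplied LD matrix does not cover every candidate variant."""


class GwasRecord(NamedTuple):
    """One variant's association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when missing
    beta: float
    se: float  # NaN until reconstructed
    pval: float
    n: float


@dataclass
class GwasTable:
    """Per-variant summary statistics for a single trait.

    ``df`` holds columns variant_id, effect_allele, other_allele, eaf, beta,
    se, pval, n (plus optional chrom/pos), unique by variant_id.
    """

    trait_name: str
    trait_unit: str
    df: pd.DataFrame
    log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trait_unit:
            raise ValueError("trait_unit must be non-empty")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant_id: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[GwasRecord]:
        cols = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
        return [GwasRecord(*row) for row in self.df[cols].itertuples(index=False, name=None)]

    def with_df(self, df: pd.DataFrame, extra_log: Iterable[tuple[str, str]] = ()) -> "GwasTable":
        return GwasTable(self.trait_name, self.trait_unit, df.reset_index(drop=True),
                         list(self.log) + list(extra_log))


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP exposure and outcome associations.

    ``bx``/``sex`` are 1-D for a single exposure or (L, K) for K exposures;
    everything is ordered by ascending ``variant_id``.
    """

    exposure_names: tuple[str, ...]
    outcome_name: str
    variant_id: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    eaf: np.ndarray
    bx: np.ndarray
    sex: np.ndarray
    by: np.ndarray
    sey: np.ndarray
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.variant_id)
        if L < 1:
            raise HarmonizationError("zero retained SNPs")
        for name in ("ea", "oa", "eaf", "bx", "sex", "by", "sey"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.variant_id)

    @property
    def n_exposures(self) -> int:
        return 1 if self.bx.ndim == 1 else self.bx.shape[1]

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask)
        return HarmonizedSet(
            self.exposure_names, self.outcome_name,
            self.variant_id[mask], self.ea[mask], self.oa[mask], self.eaf[mask],
            self.bx[mask], self.sex[mask], self.by[mask], self.sey[mask],
            list(self.exclusion_log))

    def to_frame(self) -> pd.DataFrame:
        d = {"variant_id": self.variant_id, "ea": self.ea, "oa": self.oa, "eaf": self.eaf}
        if self.bx.ndim == 1:
            d["bx"], d["sex"] = self.bx, self.sex
        else:
            for k, name in enumerate(self.exposure_names):
                d[f"bx_{name}"], d[f"sex_{name}"] = self.bx[:, k], self.sex[:, k]
        d["by"], d["sey"] = self.by, self.sey
        return pd.DataFrame(d)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        excl = Path(path).with_suffix(".exclusions.tsv")
        pd.DataFrame(self.exclusion_log, columns=["variant_id", "reason"]).to_csv(
            excl, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 exposure_names: Sequence[str] = ("exposure",),
                 outcome_name: str = "outcome") -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        bx_cols = [c for c in df.columns if c == "bx" or c.startswith("bx_")]
        sex_cols = [c for c in df.columns if c == "sex" or c.startswith("sex_")]
        if bx_cols == ["bx"]:
            bx, sex = df["bx"].to_numpy(), df["sex"].to_numpy()
            names = tuple(exposure_names)[:1]
        else:
            bx = df[bx_cols].to_numpy()
            sex = df[sex_cols].to_numpy()
            names = tuple(c[3:] for c in bx_cols)
        return cls(names, outcome_name,
                   df["variant_id"].to_numpy(dtype=object), df["ea"].to_numpy(dtype=object),
                   df["oa"].to_numpy(dtype=object), df["eaf"].to_numpy(dtype=float),
                   bx, sex, df["by"].to_numpy(dtype=float), df["sey"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# reading / validation
# ---------------------------------------------------------------------------

def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    lower = {c.lower(): c for c in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for std, aliases in COLUMN_ALIASES.items():
        if std in column_map:
            if column_map[std] not in header:
                raise FormatError(f"mapped column {column_map[std]!r} for {std!r} not in file")
            resolved[std] = column_map[std]
            continue
        for a in aliases:
            if a in lower:
                resolved[std] = lower[a]
                break
    missing = [c for c in MANDATORY if c not in resolved]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "se" not in resolved and "pval" not in resolved:
        raise FormatError("need at least one of 'se' and 'pval' columns")
    return resolved


def read_sumstats(path: str | Path, *, column_map: Mapping[str, str] | None = None,
                  trait_name: str = "", trait_unit: str = "unknown") -> GwasTable:
    """Read a delimited summary-statistics table into a validated :class:`GwasTable`.

    Rows failing a field invariant (bad alleles, eaf outside [0,1], se ≤ 0,
    pval outside (0,1]) are dropped and logged; missing se is retained as NaN
    for later :func:`reconstruct_se` when a p-value is present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise EmptyInputError(f"{path}: empty table")
    resolved = _resolve_columns(list(df.columns), column_map)
    df = df.rename(columns={v: k for k, v in resolved.items()})
    for col in ("eaf", "se", "pval", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[[c for c in ("variant_id", "effect_allele", "other_allele", "eaf",
                         "beta", "se", "pval", "n", "chrom", "pos") if c in df.columns]]

    log: list[tuple[str, str]] = []
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    def drop(mask: pd.Series, reason: str) -> None:
        for vid in df.loc[mask, "variant_id"]:
            log.append((vid, reason))

    bad = ~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES)
    drop(bad, "invalid-allele")
    same = ~bad & (df["effect_allele"] == df["other_allele"])
    drop(same, "identical-alleles")
    bad |= same
    eaf_bad = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    drop(eaf_bad & ~bad, "eaf-out-of-range")
    bad |= eaf_bad
    beta_bad = df["beta"].isna() | ~np.isfinite(df["beta"])
    drop(beta_bad & ~bad, "missing-beta")
    bad |= beta_bad
    se_bad = df["se"].notna() & (df["se"] <= 0)
    drop(se_bad & ~bad, "nonpositive-se")
    bad |= se_bad
    p_bad = df["pval"].notna() & ((df["pval"] <= 0) | (df["pval"] > 1))
    drop(p_bad & ~bad, "pval-out-of-range")
    bad |= p_bad
    neither = df["se"].isna() & df["pval"].isna()
    drop(neither & ~bad, "no-se-no-pval")
    bad |= neither
    dup = df["variant_id"].duplicated(keep="first")
    drop(dup & ~bad, "duplicate-variant")
    bad |= dup

    df = df.loc[~bad].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path}: no rows survive validation")
    n_flag = int(df["se"].isna().sum())
    if n_flag:
        logger.info("%s: %d rows need SE reconstruction from p-values", path, n_flag)
    return GwasTable(trait_name or path.stem, trait_unit, df, log)


def reconstruct_se(beta: float, pval: float) -> float:
    """Standard error implied by a beta and a two-sided normal p-value.

    se = |beta| / z with z the two-sided standard-normal quantile at ``pval``,
    computed on the log scale so that astronomically small p-values do not
    overflow.
    """
    if not (0 < pval < 1):
        raise SumstatsError(f"cannot reconstruct SE at pval={pval}")
    if beta == 0:
        raise SumstatsError("cannot reconstruct SE for beta == 0")
    se = abs(beta) / z_from_p(pval)
    if not np.isfinite(se) or se <= 0:
        raise SumstatsError(f"reconstructed SE not finite for beta={beta}, pval={pval}")
    return float(se)


def fill_missing_se(table: GwasTable) -> GwasTable:
    """Fill NaN standard errors from (beta, pval); drop rows where impossible."""
    df = table.df.copy()
    log: list[tuple[str, str]] = []
    need = df["se"].isna()
    keep = np.ones(len(df), dtype=bool)
    for i in np.flatnonzero(need.to_numpy()):
        row = df.iloc[i]
        try:
            df.iat[i, df.columns.get_loc("se")] = reconstruct_se(row["beta"], row["pval"])
        except SumstatsError:
            keep[i] = False
            log.append((row["variant_id"], "undefined-se"))
    out = df.loc[keep]
    if out.empty:
        raise EmptyInputError("no rows with usable SE")
    # fill missing p-values from (beta, se) for threshold filtering
    miss_p = out["pval"].isna()
    if miss_p.any():
        out = out.copy()
        out.loc[miss_p, "pval"] = two_sided_p(out.loc[miss_p, "beta"].to_numpy(),
                                              out.loc[miss_p, "se"].to_numpy())
    return table.with_df(out, log)


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def select_instruments(table: GwasTable, p_threshold: float = 5e-8,
                       ld: pd.DataFrame | None = None,
                       r2_threshold: float = 0.001) -> GwasTable:
    """Keep genome-wide-significant variants, greedily clumped when LD is known.

    Candidates with ``pval < p_threshold`` are visited in ascending p-value
    (variant_id breaks ties); a candidate is retained only if its squared
    correlation with every already-retained variant is below ``r2_threshold``.
    Without an LD matrix the input is treated as pre-pruned (logged).
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    df = table.df
    cand = df[df["pval"] < p_threshold].sort_values(
        ["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    log = [(vid, "pval-above-threshold") for vid in df.loc[df["pval"] >= p_threshold, "variant_id"]]
    if ld is None:
        logger.warning("%s: no LD matrix supplied; assuming input is LD-pruned", table.trait_name)
        return table.with_df(cand.sort_values("variant_id", kind="mergesort"), log)
    missing = set(cand["variant_id"]) - set(map(str, ld.index))
    if missing:
        raise IncompleteLDError(f"LD matrix missing variants: {sorted(missing)}")
    kept: list[str] = []
    for vid in cand["variant_id"]:
        r2 = ld.loc[vid, kept].to_numpy(dtype=float) ** 2 if kept else np.array([])
        if np.all(r2 < r2_threshold):
            kept.append(vid)
        else:
            log.append((vid, "ld-clumped"))
    out = cand[cand["variant_id"].isin(kept)].sort_values("variant_id", kind="mergesort")
    return table.with_df(out, log)


def exclude_blocklist(table: GwasTable, blocked_ids: Iterable[str] = DEFAULT_BLOCKLIST,
                      blocked_regions: Sequence[tuple[str, int, int]] | None = None) -> GwasTable:
    """Remove variants on a blocklist or inside blocked regions (1-based closed)."""
    blocked_ids = set(blocked_ids)
    df = table.df
    mask = df["variant_id"].isin(blocked_ids)
    log = [(vid, "blocklisted-id") for vid in df.loc[mask, "variant_id"]]
    if blocked_regions and "chrom" in df.columns and "pos" in df.columns:
        for chrom, start, end in blocked_regions:
            inreg = (df["chrom"].astype(str) == str(chrom)) & \
                    (df["pos"] >= start) & (df["pos"] <= end)
            log += [(vid, f"blocked-region-{chrom}:{start}-{end}")
                    for vid in df.loc[inreg & ~mask, "variant_id"]]
            mask |= inreg
    out = df.loc[~mask]
    if out.empty:
        logger.warning("%s: blocklist removed every variant", table.trait_name)
    return table.with_df(out, log)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def _align_pair(ref: pd.DataFrame, other: pd.DataFrame, eaf_window: tuple[float, float],
                ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Align ``other`` to ``ref``'s effect-allele orientation on shared variants.

    Returns the merged frame (ref columns suffixed _r, other _o, with other's
    beta/eaf flipped in place where needed) and the exclusion log.
    """
    lo, hi = eaf_window
    m = ref.merge(other, on="variant_id", suffixes=("_r", "_o"))
    log: list[tuple[str, str]] = []
    keep = np.ones(len(m), dtype=bool)
    flip = np.zeros(len(m), dtype=bool)
    for i, row in enumerate(m.itertuples(index=False)):
        ea_r, oa_r = row.effect_allele_r, row.other_allele_r
        ea_o, oa_o = row.effect_allele_o, row.other_allele_o
        if _is_palindromic(ea_r, oa_r):
            if {ea_o, oa_o} != {ea_r, oa_r}:
                keep[i] = False
                log.append((row.variant_id, "allele-mismatch"))
                continue
            eaf_r, eaf_o = row.eaf_r, row.eaf_o
            if not np.isfinite(eaf_r) or not np.isfinite(eaf_o):
                keep[i] = False
                log.append((row.variant_id, "palindromic-missing-eaf"))
                continue
            if lo < eaf_r < hi:
                keep[i] = False
                log.append((row.variant_id, "palindromic-intermediate-eaf"))
                continue
            # strand ambiguous: orient by EAF concordance
            eaf_aligned = eaf_o if ea_o == ea_r else 1.0 - eaf_o
            flip_letters = ea_o != ea_r
            if abs(eaf_r - eaf_aligned) <= abs(eaf_r - (1.0 - eaf_aligned)):
                flip[i] = flip_letters
            else:
                flip[i] = not flip_letters
            continue
        if (ea_o, oa_o) == (ea_r, oa_r):
            continue
        if (ea_o, oa_o) == (oa_r, ea_r):
            flip[i] = True
            continue
        cea, coa = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
        if (cea, coa) == (ea_r, oa_r):
            continue
        if (cea, coa) == (oa_r, ea_r):
            flip[i] = True
            continue
        keep[i] = False
        log.append((row.variant_id, "allele-mismatch"))
    m = m.loc[keep].copy()
    flip = flip[keep]
    m.loc[flip, "beta_o"] = -m.loc[flip, "beta_o"]
    m.loc[flip, "eaf_o"] = 1.0 - m.loc[flip, "eaf_o"]
    m["effect_allele_o"] = m["effect_allele_r"]
    m["other_allele_o"] = m["other_allele_r"]
    return m, log


def harmonize(exposure: GwasTable | Sequence[GwasTable], outcome: GwasTable,
              eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW) -> HarmonizedSet:
    """Align outcome (and any additional exposures) to the first exposure's
    effect alleles and assemble the estimator-ready :class:`HarmonizedSet`.

    Swapped alleles flip the outcome beta; strand complements are resolved;
    palindromic variants are oriented by EAF concordance and discarded when the
    first exposure's EAF lies strictly inside ``eaf_window`` (or is missing).
    Output rows are sorted by ascending variant_id.
    """
    exposures = [exposure] if isinstance(exposure, GwasTable) else list(exposure)
    ref = exposures[0].df
    log: list[tuple[str, str]] = []

    aligned_extra: list[pd.DataFrame] = []
    shared = ref
    for extra in exposures[1:]:
        m, l = _align_pair(shared, extra.df, eaf_window)
        log += l
        shared = shared[shared["variant_id"].isin(m["variant_id"])]
        aligned_extra.append(m[["variant_id", "beta_o", "se_o"]].rename(
            columns={"beta_o": f"beta::{extra.trait_name}", "se_o": f"se::{extra.trait_name}"}))
    m_out, l = _align_pair(shared, outcome.df, eaf_window)
    log += l
    merged = m_out
    for extra in aligned_extra:
        merged = merged.merge(extra, on="variant_id")
    merged = merged.sort_values("variant_id", kind="mergesort").reset_index(drop=True)
    if merged.empty:
        raise HarmonizationError(
            f"no variant survives harmonization of {[e.trait_name for e in exposures]} "
            f"with {outcome.trait_name}")

    names = tuple(e.trait_name for e in exposures)
    if len(exposures) == 1:
        bx = merged["beta_r"].to_numpy(dtype=float)
        sex = merged["se_r"].to_numpy(dtype=float)
    else:
        bx = np.column_stack([merged["beta_r"].to_numpy(dtype=float)] +
                             [merged[f"beta::{e.trait_name}"].to_numpy(dtype=float)
                              for e in exposures[1:]])
        sex = np.column_stack([merged["se_r"].to_numpy(dtype=float)] +
                              [merged[f"se::{e.trait_name}"].to_numpy(dtype=float)
                               for e in exposures[1:]])
    return HarmonizedSet(
        names, outcome.trait_name,
        merged["variant_id"].to_numpy(dtype=object),
        merged["effect_allele_r"].to_numpy(dtype=object),
        merged["other_allele_r"].to_numpy(dtype=object),
        merged["eaf_r"].to_numpy(dtype=float),
        bx, sex,
        merged["beta_o"].to_numpy(dtype=float),
        merged["se_o"].to_numpy(dtype=float),
        log)
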