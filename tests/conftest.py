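import numpy as np
import pandas as pd
import pytest

from summr.sumstats import GwasTable, HarmonizedSet


def make_hset(bx, by, sey, sex=None, variant_ids=None, names=("x",), outcome="y"):
    """Build a HarmonizedSet straight from arrays (single or multi exposure)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sey = np.asarray(sey, dtype=float)
    L = len(by)
    if sex is None:
        sex = np.full_like(bx, 1e-6)
    else:
        sex = np.asarray(sex, dtype=float)
    if variant_ids is None:
        variant_ids = np.array([f"rs{i:06d}" for i in range(1, L + 1)], dtype=object)
    else:
        variant_ids = np.asarray(variant_ids, dtype=object)
    return HarmonizedSet(
        tuple(names), outcome, variant_ids,
        np.array(["A"] * L, dtype=object), np.array(["G"] * L, dtype=object),
        np.full(L, 0.5), bx, sex, by, sey)


def make_table(rows, trait_name="trait", trait_unit="SD"):
    """GwasTable from a list of dicts; unspecified fields get benign defaults."""
    defaults = {"eaf": 0.3, "se": 0.01, "n": 100_000.0}
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d.setdefault("pval", 1e-10)
        full.append(d)
    df = pd.DataFrame(full)
    order = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
    extra = [c for c in df.columns if c not in order]
    return GwasTable(trait_name, trait_unit, df[order + extra])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tsv_writer(tmp_path):
    def write(df: pd.DataFrame, name: str = "table.tsv"):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path
    return write
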