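import numpy as np
import pandas as pd
import pytest
from scipy import stats

from summr.sumstats import (DEFAULT_BLOCKLIST, EmptyInputError, FormatError,
                            GwasTable, HarmonizationError, IncompleteLDError,
                            exclude_blocklist, fill_missing_se, harmonize,
                            read_sumstats, reconstruct_se, select_instruments)
from conftest import make_table


def _tsv(tmp_path, df, name="x.tsv"):
    p = tmp_path / name
    df.to_csv(p, sep="\t", index=False)
    return p


class TestReadSumstats:
    def test_identity_read_through(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1", "rs2", "rs3"], "A1": ["A", "C", "G"], "A2": ["G", "T", "A"],
            "EAF": [0.2, 0.5, 0.7], "BETA": [0.1, -0.2, 0.05],
            "SE": [0.01, 0.02, 0.01], "P": [1e-20, 1e-22, 1e-8], "N": [1000] * 3})
        t = read_sumstats(_tsv(tmp_path, df), trait_name="t", trait_unit="SD")
        assert len(t) == 3
        assert list(t.df["variant_id"]) == ["rs1", "rs2", "rs3"]
        assert t.df["beta"].tolist() == [0.1, -0.2, 0.05]

    def test_identical_alleles_dropped_and_logged(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1", "rs2"], "A1": ["A", "C"], "A2": ["A", "T"],
            "BETA": [0.1, 0.2], "SE": [0.01, 0.01]})
        t = read_sumstats(_tsv(tmp_path, df))
        assert len(t) == 1
        assert ("rs1", "identical-alleles") in t.log

    def test_missing_se_flagged_then_reconstructed(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1"], "A1": ["A"], "A2": ["G"], "BETA": [0.10], "P": [0.05]})
        t = read_sumstats(_tsv(tmp_path, df))
        assert np.isnan(t.df["se"].iloc[0])
        filled = fill_missing_se(t)
        assert filled.df["se"].iloc[0] == pytest.approx(0.10 / 1.9599639845, rel=1e-6)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "BETA": [0.1], "SE": [0.01]})
        with pytest.raises(FormatError, match="other_allele"):
            read_sumstats(_tsv(tmp_path, df))

    def test_empty_after_validation(self, tmp_path):
        df = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["A"],
                           "BETA": [0.1], "SE": [0.01]})
        with pytest.raises(EmptyInputError):
            read_sumstats(_tsv(tmp_path, df))

    def test_comma_delimited_accepted(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("SNP,A1,A2,BETA,SE\nrs1,A,G,0.1,0.01\n")
        assert len(read_sumstats(p)) == 1


class TestReconstructSE:
    def test_unit_z(self):
        assert reconstruct_se(1.0, 0.3173105) == pytest.approx(1.0, abs=1e-5)

    def test_quantile_oracle(self):
        # independent oracle: scipy two-sided normal quantile
        z = stats.norm.isf(0.05 / 2)
        assert reconstruct_se(0.10, 0.05) == pytest.approx(0.10 / z, rel=1e-12)
        assert reconstruct_se(0.10, 0.05) == pytest.approx(0.051021, abs=1e-6)

    def test_sign_symmetry(self):
        assert reconstruct_se(-0.2, 0.05) == pytest.approx(reconstruct_se(0.2, 0.05))
        assert reconstruct_se(-0.2, 0.05) == pytest.approx(0.102043, abs=1e-6)

    @pytest.mark.parametrize("beta,pval", [(0.0, 0.5), (0.1, 1.0), (0.1, 0.0), (0.1, 1.5)])
    def test_undefined(self, beta, pval):
        with pytest.raises(Exception):
            reconstruct_se(beta, pval)

    def test_tiny_pval_no_overflow(self):
        se = reconstruct_se(0.5, 1e-300)
        assert np.isfinite(se) and se > 0

    def test_round_trip_p(self):
        from summr._stats import two_sided_p
        for pval in (0.7, 0.05, 1e-8, 1e-100, 1e-250):
            se = reconstruct_se(0.37, pval)
            assert two_sided_p(0.37, se) == pytest.approx(pval, rel=1e-10)


class TestSelectInstruments:
    def _table(self, pvals, ids=None):
        ids = ids or [f"rs{i}" for i in range(len(pvals))]
        return make_table([{"variant_id": v, "effect_allele": "A", "other_allele": "G",
                            "beta": 0.1, "pval": p} for v, p in zip(ids, pvals)])

    def test_threshold_count(self):
        t = select_instruments(self._table([1e-9, 1e-7, 1e-12, 0.01, 4e-8]))
        assert len(t) == 3

    def test_greedy_clump_keeps_smaller_p(self):
        t = self._table([1e-12, 1e-9], ids=["rsA", "rsB"])
        ld = pd.DataFrame([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]],
                          index=["rsA", "rsB"], columns=["rsA", "rsB"])
        out = select_instruments(t, ld=ld, r2_threshold=0.001)
        assert list(out.df["variant_id"]) == ["rsA"]

    def test_brute_force_pairwise_oracle(self, rng):
        n = 10
        ids = [f"rs{i}" for i in range(n)]
        pvals = rng.uniform(1e-30, 1e-9, n)
        corr = rng.uniform(-1, 1, (n, n))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        ld = pd.DataFrame(corr, index=ids, columns=ids)
        out = select_instruments(self._table(pvals, ids), ld=ld, r2_threshold=0.1)
        kept = list(out.df["variant_id"])
        # oracle: all retained pairs below threshold ...
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.loc[a, b] ** 2 < 0.1
        # ... and greedy order means every dropped candidate clashes with a
        # better-ranked retained one
        order = sorted(ids, key=lambda v: (pvals[ids.index(v)], v))
        for v in order:
            if v in kept:
                continue
            better = [k for k in kept if pvals[ids.index(k)] < pvals[ids.index(v)]]
            assert any(ld.loc[v, k] ** 2 >= 0.1 for k in better)

    def test_incomplete_ld_raises(self):
        t = self._table([1e-12, 1e-9], ids=["rsA", "rsB"])
        ld = pd.DataFrame([[1.0]], index=["rsA"], columns=["rsA"])
        with pytest.raises(IncompleteLDError):
            select_instruments(t, ld=ld)

    def test_row_order_invariance(self, rng):
        pvals = list(rng.uniform(1e-30, 1e-9, 8))
        t1 = self._table(pvals)
        perm = rng.permutation(8)
        t2 = t1.with_df(t1.df.iloc[perm])
        out1 = select_instruments(t1)
        out2 = select_instruments(t2)
        assert list(out1.df["variant_id"]) == list(out2.df["variant_id"])


class TestBlocklist:
    def test_default_removes_hfe_variants(self):
        t = make_table([{"variant_id": v, "effect_allele": "A", "other_allele": "G",
                         "beta": 0.1} for v in ["rs1800562", "rs1799945", "rs42"]])
        out = exclude_blocklist(t)
        assert list(out.df["variant_id"]) == ["rs42"]
        assert ("rs1800562", "blocklisted-id") in out.log

    def test_empty_blocklist_identity(self):
        t = make_table([{"variant_id": "rs1800562", "effect_allele": "A",
                         "other_allele": "G", "beta": 0.1}])
        assert len(exclude_blocklist(t, blocked_ids=set())) == 1

    def test_region_block(self):
        rows = [{"variant_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
                 "beta": 0.1, "chrom": "6", "pos": 100 * i} for i in range(1, 6)]
        t = make_table(rows)
        out = exclude_blocklist(t, blocked_ids=set(), blocked_regions=[("6", 150, 350)])
        assert len(out) == 3  # pos 200 and 300 removed


class TestHarmonize:
    def _exp(self, **kw):
        row = {"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
               "eaf": 0.2, "beta": 0.1, "se": 0.01}
        row.update(kw)
        return make_table([row], trait_name="exp")

    def _out(self, **kw):
        row = {"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
               "eaf": 0.2, "beta": 0.05, "se": 0.02}
        row.update(kw)
        return make_table([row], trait_name="out")

    def test_allele_swap_flips_sign(self):
        h = harmonize(self._exp(), self._out(effect_allele="G", other_allele="A", eaf=0.8))
        assert h.by[0] == pytest.approx(-0.05)
        assert h.eaf[0] == pytest.approx(0.2)

    def test_strand_complement(self):
        h = harmonize(self._exp(), self._out(effect_allele="T", other_allele="C"))
        assert h.by[0] == pytest.approx(0.05)

    def test_strand_complement_swapped(self):
        h = harmonize(self._exp(), self._out(effect_allele="C", other_allele="T", eaf=0.8))
        assert h.by[0] == pytest.approx(-0.05)

    def test_palindromic_intermediate_discarded(self):
        exp = self._exp(effect_allele="A", other_allele="T", eaf=0.50)
        out = self._out(effect_allele="A", other_allele="T", eaf=0.50,
                        variant_id="rs2")
        exp2 = make_table([exp.df.iloc[0].to_dict(),
                           {"variant_id": "rs2", "effect_allele": "C", "other_allele": "G",
                            "eaf": 0.1, "beta": 0.3, "se": 0.01}], trait_name="exp")
        out2 = make_table([{"variant_id": "rs1", "effect_allele": "A", "other_allele": "T",
                            "eaf": 0.5, "beta": 0.05, "se": 0.02},
                           {"variant_id": "rs2", "effect_allele": "C", "other_allele": "G",
                            "eaf": 0.1, "beta": 0.2, "se": 0.02}], trait_name="out")
        h = harmonize(exp2, out2)
        assert list(h.variant_id) == ["rs2"]
        assert ("rs1", "palindromic-intermediate-eaf") in h.exclusion_log

    def test_palindromic_eaf_boundary_retained(self):
        # strict window: eaf exactly 0.42 is kept
        h = harmonize(self._exp(effect_allele="A", other_allele="T", eaf=0.42),
                      self._out(effect_allele="A", other_allele="T", eaf=0.42))
        assert h.n_snps == 1

    def test_palindromic_eaf_concordance_oracle(self):
        # exposure eaf 0.10, outcome eaf 0.88: concordant only under flip
        h = harmonize(self._exp(effect_allele="A", other_allele="T", eaf=0.10),
                      self._out(effect_allele="A", other_allele="T", eaf=0.88))
        eaf_exp, eaf_out = 0.10, 0.88
        flip_oracle = abs(eaf_exp - eaf_out) > abs(eaf_exp - (1 - eaf_out))
        assert flip_oracle
        assert h.by[0] == pytest.approx(-0.05)
        assert h.eaf[0] == pytest.approx(0.10)

    def test_palindromic_missing_eaf_discarded(self):
        exp = make_table([
            {"variant_id": "rs1", "effect_allele": "A", "other_allele": "T",
             "eaf": np.nan, "beta": 0.1, "se": 0.01},
            {"variant_id": "rs2", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.2, "beta": 0.1, "se": 0.01}], trait_name="exp")
        out = make_table([
            {"variant_id": "rs1", "effect_allele": "A", "other_allele": "T",
             "eaf": 0.2, "beta": 0.1, "se": 0.01},
            {"variant_id": "rs2", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.2, "beta": 0.1, "se": 0.01}], trait_name="out")
        h = harmonize(exp, out)
        assert list(h.variant_id) == ["rs2"]
        assert ("rs1", "palindromic-missing-eaf") in h.exclusion_log

    def test_irreconcilable_discarded(self):
        exp = make_table([
            {"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01},
            {"variant_id": "rs2", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01}], trait_name="exp")
        out = make_table([
            {"variant_id": "rs1", "effect_allele": "A", "other_allele": "C",
             "beta": 0.1, "se": 0.01},
            {"variant_id": "rs2", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01}], trait_name="out")
        h = harmonize(exp, out)
        assert list(h.variant_id) == ["rs2"]
        assert ("rs1", "allele-mismatch") in h.exclusion_log

    def test_no_shared_variant_raises(self):
        with pytest.raises(HarmonizationError):
            harmonize(self._exp(), self._out(variant_id="rs999"))

    def test_output_sorted_by_variant_id(self):
        rows_e = [{"variant_id": v, "effect_allele": "A", "other_allele": "G",
                   "beta": 0.1, "se": 0.01} for v in ["rsB", "rsA", "rsC"]]
        rows_o = [{"variant_id": v, "effect_allele": "A", "other_allele": "G",
                   "beta": 0.2, "se": 0.01} for v in ["rsC", "rsB", "rsA"]]
        h = harmonize(make_table(rows_e, trait_name="e"), make_table(rows_o, trait_name="o"))
        assert list(h.variant_id) == ["rsA", "rsB", "rsC"]

    def test_idempotence(self):
        exp = make_table([
            {"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.2, "beta": 0.1, "se": 0.01},
            {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
             "eaf": 0.7, "beta": -0.2, "se": 0.02}], trait_name="exp")
        out = make_table([
            {"variant_id": "rs1", "effect_allele": "G", "other_allele": "A",
             "eaf": 0.8, "beta": 0.05, "se": 0.02},
            {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
             "eaf": 0.7, "beta": 0.3, "se": 0.02}], trait_name="out")
        h1 = harmonize(exp, out)
        # re-express the harmonized set as tables and harmonize again
        exp2 = make_table([
            {"variant_id": v, "effect_allele": ea, "other_allele": oa, "eaf": f,
             "beta": b, "se": s}
            for v, ea, oa, f, b, s in zip(h1.variant_id, h1.ea, h1.oa, h1.eaf,
                                          h1.bx, h1.sex)], trait_name="exp")
        out2 = make_table([
            {"variant_id": v, "effect_allele": ea, "other_allele": oa, "eaf": f,
             "beta": b, "se": s}
            for v, ea, oa, f, b, s in zip(h1.variant_id, h1.ea, h1.oa, h1.eaf,
                                          h1.by, h1.sey)], trait_name="out")
        h2 = harmonize(exp2, out2)
        np.testing.assert_allclose(h2.bx, h1.bx)
        np.testing.assert_allclose(h2.by, h1.by)
        assert list(h2.variant_id) == list(h1.variant_id)

    def test_orientation_invariance_of_estimates(self):
        from summr.estimators import ivw_mre
        rows_e, rows_o, rows_ef, rows_of = [], [], [], []
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rng = np.random.default_rng(3)
        for i in range(6):
            ea, oa = ("A", "G") if i % 2 else ("C", "T")
            b, s, f = rng.normal(0.1, 0.02), 0.01, rng.uniform(0.1, 0.35)
            bo = 0.3 * b + rng.normal(0, 0.01)
            rows_e.append({"variant_id": f"rs{i}", "effect_allele": ea, "other_allele": oa,
                           "eaf": f, "beta": b, "se": s})
            rows_o.append({"variant_id": f"rs{i}", "effect_allele": ea, "other_allele": oa,
                           "eaf": f, "beta": bo, "se": 0.02})
            # flipped representation: swap labels, negate beta, complement strand
            rows_ef.append({"variant_id": f"rs{i}", "effect_allele": oa, "other_allele": ea,
                            "eaf": 1 - f, "beta": -b, "se": s})
            rows_of.append({"variant_id": f"rs{i}", "effect_allele": comp[oa],
                            "other_allele": comp[ea], "eaf": 1 - f, "beta": -bo, "se": 0.02})
        h1 = harmonize(make_table(rows_e, trait_name="e"), make_table(rows_o, trait_name="o"))
        h2 = harmonize(make_table(rows_ef, trait_name="e"), make_table(rows_of, trait_name="o"))
        e1, e2 = ivw_mre(h1), ivw_mre(h2)
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.se == pytest.approx(e2.se, rel=1e-12)

    def test_multi_exposure_alignment(self):
        e1 = make_table([{"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
                          "eaf": 0.2, "beta": 0.1, "se": 0.01},
                         {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
                          "eaf": 0.6, "beta": 0.2, "se": 0.01}], trait_name="e1")
        e2 = make_table([{"variant_id": "rs1", "effect_allele": "G", "other_allele": "A",
                          "eaf": 0.8, "beta": -0.4, "se": 0.01},
                         {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
                          "eaf": 0.6, "beta": 0.5, "se": 0.01}], trait_name="e2")
        out = make_table([{"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
                           "eaf": 0.2, "beta": 0.05, "se": 0.02},
                          {"variant_id": "rs2", "effect_allele": "T", "other_allele": "C",
                           "eaf": 0.4, "beta": -0.1, "se": 0.02}], trait_name="o")
        h = harmonize([e1, e2], out)
        assert h.bx.shape == (2, 2)
        np.testing.assert_allclose(h.bx[:, 0], [0.1, 0.2])
        np.testing.assert_allclose(h.bx[:, 1], [0.4, 0.5])  # rs1 flipped to e1 orientation
        np.testing.assert_allclose(h.by, [0.05, 0.1])

    def test_tsv_round_trip(self, tmp_path):
        h = harmonize(self._exp(), self._out())
        p = tmp_path / "set.tsv"
        h.to_tsv(p)
        from summr.sumstats import HarmonizedSet
        h2 = HarmonizedSet.from_tsv(p)
        np.testing.assert_allclose(h2.bx, h.bx)
        np.testing.assert_allclose(h2.by, h.by)
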