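import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facendo import gwas


class TestCodeGenotype:
    def test_autosomal_counts_major_allele(self):
        assert gwas.code_genotype(("A", "G"), major="A", chrom="1", sex=0) == 1
        assert gwas.code_genotype(("A", "A"), major="A", chrom="1", sex=1) == 2
        assert gwas.code_genotype(("G", "G"), major="A", chrom="1", sex=0) == 0

    def test_male_x_hemizygous_coding(self):
        assert gwas.code_genotype(("A",), major="A", chrom="X", sex=1) == 2
        assert gwas.code_genotype(("G",), major="A", chrom="X", sex=1) == 0

    def test_female_x_diploid(self):
        assert gwas.code_genotype(("A", "G"), major="A", chrom="X", sex=0) == 1

    def test_heterozygous_male_x_rejected(self):
        with pytest.raises(ValueError, match="hemizygous"):
            gwas.code_genotype(("A", "G"), major="A", chrom="X", sex=1)


class TestSNPRegression:
    def test_exact_linear_relation(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        beta, se, t, p, n = gwas.snp_regression(2.0 * g, g)
        assert beta == pytest.approx(2.0)
        assert p <= np.finfo(float).tiny

    def test_eight_point_closed_form_oracle(self):
        dosage = np.array([0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
        score = np.array([1.1, 0.8, 1.9, 2.3, 2.1, 3.2, 2.8, 3.4])
        beta, se, t, p, n = gwas.snp_regression(score, dosage)
        # independent oracle: statsmodels OLS
        import statsmodels.api as sm

        fit = sm.OLS(score, sm.add_constant(dosage)).fit()
        assert beta == pytest.approx(fit.params[1], abs=1e-10)
        assert se == pytest.approx(fit.bse[1], abs=1e-10)
        assert t == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert p == pytest.approx(fit.pvalues[1], rel=1e-8)
        assert n == 8

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gwas.snp_regression(np.arange(10.0), np.ones(10))


class TestIVWMeta:
    def test_single_study_identity(self):
        beta, se, z, p = gwas.ivw_meta([0.3], [0.1])
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.1)
        assert z == pytest.approx(3.0)

    def test_hand_computed_weights(self):
        # w = (100, 25): beta = (100*0.2 + 25*0.4)/125 = 0.24; se = 125^-0.5
        beta, se, _, _ = gwas.ivw_meta([0.2, 0.4], [0.1, 0.2])
        assert beta == pytest.approx(0.24, abs=1e-3)
        assert se == pytest.approx(0.0894, abs=1e-3)

    def test_equal_ses_average(self):
        beta, se, _, _ = gwas.ivw_meta([0.1, 0.5], [0.2, 0.2])
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.2 / np.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gwas.ivw_meta([], [])

    @settings(deadline=None, derandomize=True)
    @given(st.permutations([0, 1, 2]))
    def test_cohort_order_invariance(self, order):
        betas = np.array([0.1, -0.2, 0.4])[order]
        ses = np.array([0.05, 0.1, 0.2])[order]
        ref = gwas.ivw_meta([0.1, -0.2, 0.4], [0.05, 0.1, 0.2])
        out = gwas.ivw_meta(betas, ses)
        assert out == pytest.approx(ref)

    def test_matches_pooled_ols_for_homogeneous_cohorts(self):
        g = np.random.default_rng(12)
        dosage = g.binomial(2, 0.4, size=2000).astype(float)
        score = 0.1 * dosage + g.normal(size=2000)
        halves = [(score[:1000], dosage[:1000]), (score[1000:], dosage[1000:])]
        per = [gwas.snp_regression(s, d) for s, d in halves]
        beta_meta, se_meta, _, _ = gwas.ivw_meta(
            [r[0] for r in per], [r[1] for r in per]
        )
        beta_pool, se_pool, *_ = gwas.snp_regression(score, dosage)
        assert beta_meta == pytest.approx(beta_pool, rel=0.02, abs=0.005)
        assert se_meta == pytest.approx(se_pool, rel=0.02)


class TestClump:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p", "trait"])

    def test_window_example(self):
        assoc = self._assoc(
            [
                ["rs1", "1", 100_000, 1e-10, "t"],
                ["rs2", "1", 400_000, 1e-9, "t"],
                ["rs3", "1", 700_000, 1e-8, "t"],
            ]
        )
        loci = gwas.clump(assoc, window_bp=500_000, p_threshold=5e-8)
        assert len(loci) == 2
        assert loci[0].lead_snp == "rs1"
        assert set(loci[0].members) == {"rs1", "rs2"}
        assert loci[1].lead_snp == "rs3"

    def test_no_significant_snp_empty(self):
        assoc = self._assoc([["rs1", "1", 100, 1e-4, "t"]])
        assert gwas.clump(assoc) == []

    def test_loci_are_disjoint_and_cover_significant(self):
        g = np.random.default_rng(13)
        n = 200
        assoc = self._assoc(
            [
                [f"rs{i}", str(g.integers(1, 4)), int(g.integers(1, 5_000_000)), 10.0 ** -g.uniform(4, 12), "t"]
                for i in range(n)
            ]
        )
        loci = gwas.clump(assoc)
        members = [s for l in loci for s in l.members]
        assert len(members) == len(set(members))
        sig = set(assoc.loc[assoc["p"] < 5e-8, "snp"])
        lead_windows = {(l.chrom, *l.window) for l in loci}
        for snp in sig:
            assert snp in set(members) or any(
                assoc.set_index("snp").at[snp, "chrom"] == c and lo <= assoc.set_index("snp").at[snp, "pos"] <= hi
                for c, lo, hi in lead_windows
            )

    def test_best_p_across_traits_defines_lead(self):
        assoc = self._assoc(
            [
                ["rs1", "1", 100_000, 1e-9, "a"],
                ["rs1", "1", 100_000, 1e-12, "b"],
                ["rs2", "1", 150_000, 1e-10, "a"],
            ]
        )
        loci = gwas.clump(assoc)
        assert len(loci) == 1
        assert loci[0].lead_snp == "rs1"
        assert loci[0].best_trait == "b"


class TestThresholds:
    def test_identity_for_single_trait(self):
        gw, sw = gwas.thresholds(5e-8, 1)
        assert gw == sw == 5e-8

    def test_arithmetic(self):
        assert gwas.thresholds(5e-8, 10)[1] == pytest.approx(5e-9)

    def test_overlap_percentage(self):
        assert gwas.overlap_percentage(22, 29) == 76
        with pytest.raises(ValueError):
            gwas.overlap_percentage(5, 3)


class TestAssociationScan:
    def test_matches_per_snp_regression(self):
        g = np.random.default_rng(14)
        dos = g.binomial(2, 0.3, size=(150, 5)).astype(float)
        meta = pd.DataFrame(
            {
                "snp": [f"rs{j}" for j in range(5)],
                "chrom": "1",
                "pos": np.arange(5) * 10_000 + 1,
                "allele_major": "A",
                "allele_minor": "G",
                "maf": 0.3,
            }
        )
        table = gwas.GenotypeTable(dos, meta)
        scores = pd.DataFrame({"seg1": g.normal(size=150)})
        out = gwas.association_scan(scores, table, cohort="US")
        for j in range(5):
            beta, se, t, p, n = gwas.snp_regression(scores["seg1"], dos[:, j])
            row = out[out["snp"] == f"rs{j}"].iloc[0]
            assert row["beta"] == pytest.approx(beta, abs=1e-12)
            assert row["se"] == pytest.approx(se, abs=1e-12)
            assert row["p"] == pytest.approx(p, rel=1e-9)
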