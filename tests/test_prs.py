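import numpy as np
import pandas as pd
import pytest

from facendo import prs
from facendo import synthdata as syn
from facendo.gwas import GenotypeTable


def _table(dosages, chrom="1", spacing=10_000, major="A", minor="G"):
    m = dosages.shape[1]
    meta = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
            "allele_major": major,
            "allele_minor": minor,
            "maf": 0.3,
        }
    )
    return GenotypeTable(dosages.astype(float), meta)


def _sumstats(table, betas, pvals):
    meta = table.snp_meta
    return pd.DataFrame(
        {
            "SNP": meta["snp"],
            "CHR": meta["chrom"],
            "BP": meta["pos"],
            "A1": meta["allele_major"],
            "A2": meta["allele_minor"],
            "BETA": betas,
            "SE": 0.1,
            "P": pvals,
        }
    )


class TestLDr2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1, 0, 2.0])
        assert prs.ld_r2(v, v) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        gs = syn.GenoSpec(n_snps=30, ld_block_rho=0.0, maf_range=(0.2, 0.5), seed=1)
        gt = syn.simulate_genotypes(5000, gs)
        vals = [
            prs.ld_r2(gt.dosages[:, i], gt.dosages[:, j])
            for i in range(10)
            for j in range(10, 20)
        ]
        assert np.median(vals) < 0.01

    def test_ar_pair_matches_generator_target(self):
        gs = syn.GenoSpec(
            n_snps=20, ld_block_rho=0.6, block_size=10, maf_range=(0.3, 0.5), seed=2
        )
        gt = syn.simulate_genotypes(5000, gs)
        r2 = np.mean(
            [prs.ld_r2(gt.dosages[:, j], gt.dosages[:, j + 1]) for j in range(9)]
        )
        assert abs(r2 - 0.36) < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            prs.ld_r2(np.ones(10), np.arange(10.0))


class TestLDClump:
    def test_uncorrelated_snps_all_retained(self):
        g = np.random.default_rng(3)
        gt = _table(g.binomial(2, 0.4, size=(2000, 8)))
        ss = _sumstats(gt, 0.1, np.linspace(1e-6, 1e-2, 8))
        kept = prs.ld_clump(ss, gt, r2_thresh=0.1, window_bp=250_000)
        assert len(kept) == 8

    def test_correlated_pair_keeps_best_p(self):
        g = np.random.default_rng(4)
        a = g.binomial(2, 0.4, size=2000).astype(float)
        noise = g.binomial(1, 0.05, size=2000)
        b = np.clip(a + noise, 0, 2)  # r2 ~ 0.9
        gt = _table(np.column_stack([a, b]))
        ss = _sumstats(gt, 0.1, [1e-6, 1e-3])
        kept = prs.ld_clump(ss, gt)
        assert kept["SNP"].tolist() == ["rs1"]

    def test_planted_blocks_keep_one_each(self):
        gs = syn.GenoSpec(
            n_snps=15, ld_block_rho=0.9, block_size=5, n_chrom=1,
            spacing_bp=10_000, maf_range=(0.3, 0.5), seed=5,
        )
        gt = syn.simulate_genotypes(3000, gs)
        g = np.random.default_rng(6)
        ss = _sumstats(gt, 0.1, g.uniform(1e-8, 1e-2, size=15))
        ss["CHR"] = gt.snp_meta["chrom"]
        ss["BP"] = gt.snp_meta["pos"]
        ss["A1"] = gt.snp_meta["allele_major"]
        ss["A2"] = gt.snp_meta["allele_minor"]
        kept = prs.ld_clump(ss, gt, r2_thresh=0.1, window_bp=250_000)
        # oracle: the generator's block map - exactly one survivor per block,
        # and it is that block's best-p SNP
        blocks = [range(0, 5), range(5, 10), range(10, 15)]
        for block in blocks:
            names = {f"rs{j + 1}" for j in block}
            surv = kept[kept["SNP"].isin(names)]
            assert len(surv) == 1
            best = ss[ss["SNP"].isin(names)].sort_values("P").iloc[0]["SNP"]
            assert surv.iloc[0]["SNP"] == best

    def test_empty_intersection_rejected(self):
        g = np.random.default_rng(7)
        gt = _table(g.binomial(2, 0.4, size=(100, 3)))
        ss = _sumstats(gt, 0.1, [0.1, 0.2, 0.3])
        ss["SNP"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="reference"):
            prs.ld_clump(ss, gt)


class TestPRSScore:
    def test_threshold_below_all_p_gives_zero(self):
        g = np.random.default_rng(8)
        gt = _table(g.binomial(2, 0.4, size=(50, 3)))
        ss = _sumstats(gt, 0.5, [1e-3, 1e-4, 1e-5])
        assert np.all(prs.prs_score(gt, ss, threshold=1e-9) == 0.0)

    def test_hand_computed_sum(self):
        gt = _table(np.array([[2.0, 1.0]]))
        ss = _sumstats(gt, [0.5, -1.0], [1e-8, 1e-8])
        score = prs.prs_score(gt, ss, threshold=1.0)
        assert score[0] == pytest.approx(0.0)  # 0.5*2 - 1.0*1

    def test_linearity_in_betas(self):
        g = np.random.default_rng(9)
        gt = _table(g.binomial(2, 0.4, size=(30, 4)))
        ss = _sumstats(gt, [0.1, 0.2, -0.3, 0.4], [0.2, 0.4, 0.6, 0.8])
        doubled = ss.assign(BETA=2 * ss["BETA"])
        assert np.allclose(
            prs.prs_score(gt, doubled, 1.0), 2 * prs.prs_score(gt, ss, 1.0)
        )

    def test_allele_flip_leaves_scores_unchanged(self):
        g = np.random.default_rng(10)
        gt = _table(g.binomial(2, 0.4, size=(40, 3)))
        ss = _sumstats(gt, [0.2, -0.5, 0.3], [0.1, 0.1, 0.1])
        flipped = ss.copy()
        flipped[["A1", "A2"]] = flipped[["A2", "A1"]].to_numpy()
        flipped["BETA"] = -flipped["BETA"]
        assert np.allclose(prs.prs_score(gt, ss, 1.0), prs.prs_score(gt, flipped, 1.0))

    def test_snp_order_invariance(self):
        g = np.random.default_rng(11)
        gt = _table(g.binomial(2, 0.4, size=(40, 4)))
        ss = _sumstats(gt, [0.1, 0.2, 0.3, 0.4], [0.01, 0.02, 0.03, 0.04])
        shuffled = ss.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert np.allclose(prs.prs_score(gt, ss, 1.0), prs.prs_score(gt, shuffled, 1.0))

    def test_nested_inclusion_sets(self):
        g = np.random.default_rng(12)
        gt = _table(g.binomial(2, 0.4, size=(20, 6)))
        ss = _sumstats(gt, 0.3, [1e-6, 1e-4, 1e-3, 0.05, 0.3, 0.9])
        mat = prs.prs_matrix(gt, ss, grid=np.array([1e-5, 1e-2, 0.1, 1.0]))
        counts = [(ss["P"] <= t).sum() for t in mat.columns]
        assert counts == sorted(counts)
        # each increment adds SNPs, never removes: columns differ by new terms only
        base = prs.prs_score(gt, ss, 1e-5)
        assert np.allclose(mat.iloc[:, 0], base)


class TestPRSScan:
    def test_causal_association_detected_and_null_flat(self):
        g = np.random.default_rng(13)
        n = 500
        gt = _table(g.binomial(2, 0.4, size=(n, 5)))
        ss = _sumstats(gt, [0.5, 0.4, 0.3, 0.2, 0.1], [1e-8, 1e-6, 1e-4, 1e-2, 0.5])
        mat = prs.prs_matrix(gt, ss, grid=np.array([1e-7, 1e-3, 1.0]))
        causal_trait = mat.iloc[:, 2] * 0.5 + g.normal(size=n)
        null_trait = g.normal(size=n)
        scan = prs.prs_scan(mat, pd.DataFrame({"causal": causal_trait, "null": null_trait}))
        min_p = scan.attrs["min_p"]
        assert min_p["causal"] < 1e-6
        assert min_p["causal"] < min_p["null"]

    def test_constant_prs_column_skipped(self):
        g = np.random.default_rng(14)
        gt = _table(g.binomial(2, 0.4, size=(50, 2)))
        ss = _sumstats(gt, [0.1, 0.2], [1e-3, 1e-2])
        mat = prs.prs_matrix(gt, ss, grid=np.array([1e-9, 1e-2, 1.0]))  # first: no SNPs
        scan = prs.prs_scan(mat, pd.DataFrame({"t": g.normal(size=50)}))
        assert set(scan["threshold"]) == {1e-2, 1.0}

    def test_default_grid_matches_stated_range_and_step(self):
        grid = prs.default_threshold_grid()
        assert grid[0] == pytest.approx(5e-8)
        assert grid[-1] == pytest.approx(1.0)
        steps = np.diff(grid)[1:]
        assert np.allclose(steps, 5e-5)
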