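"""Variant QC, LD clumping, polygenic scores, association scan."""

import numpy as np
import pandas as pd
import pytest

from neuroaging import genetics, synth
from neuroaging.exceptions import DegenerateInputError
from neuroaging.synth.genotypes import GenotypeSet


def _toy_genotypes(dosages: np.ndarray, pos=None, maf=None, info=None, call_rate=None):
    n, p = dosages.shape
    snps = [f"rs{j}" for j in range(p)]
    snp_info = pd.DataFrame(
        {
            "snp": snps,
            "chrom": 1,
            "pos": pos if pos is not None else np.arange(p) * 10_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf if maf is not None else np.nanmean(dosages, axis=0) / 2,
            "call_rate": call_rate if call_rate is not None else 1.0,
            "info": info if info is not None else 0.99,
        }
    )
    d = pd.DataFrame(dosages, index=[f"S{i}" for i in range(n)], columns=snps)
    d.index.name = "subject_id"
    return GenotypeSet(d, snp_info)


class TestVariantQC:
    def test_all_pass_is_identity(self):
        geno, _ = synth.generate_genotypes(n_subjects=100, n_snps=10, seed=0)
        kept, counts = genetics.variant_qc(geno)
        assert list(kept.snps) == list(geno.snps)
        assert sum(counts.values()) == 0

    def test_one_failure_per_rule_filtered(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 3, size=(200, 5)).astype(float)
        D[: int(0.1 * 200), 1] = np.nan          # call rate 90% < 95%
        maf = np.array([0.3, 0.3, 0.001, 0.3, 0.3])   # SNP2 fails MAF
        info = np.array([0.99, 0.99, 0.99, 0.5, 0.99])  # SNP3 fails INFO
        geno = _toy_genotypes(D, maf=maf, info=info)
        kept, counts = genetics.variant_qc(geno)
        survivors = {"rs0", "rs4"}
        assert set(kept.snps) == survivors
        # brute-force filter oracle
        brute = {
            s for j, s in enumerate(geno.snps)
            if (1 - np.isnan(D[:, j]).mean()) >= 0.95 and maf[j] >= 0.005 and info[j] >= 0.8
        }
        assert brute == survivors
        assert counts == {"call_rate": 1, "maf": 1, "info": 1}

    def test_default_thresholds(self):
        import inspect

        sig = inspect.signature(genetics.variant_qc)
        assert sig.parameters["max_missing"].default == 0.05
        assert sig.parameters["min_maf"].default == 0.005
        assert sig.parameters["min_info"].default == 0.8


class TestLDr2:
    def test_identical_snps(self):
        a = np.array([0, 1, 2, 1, 0])
        assert genetics.ld_r2(a, a) == pytest.approx(1.0)

    def test_hand_computation(self):
        a = np.array([0, 1, 2, 2], dtype=float)
        b = np.array([0, 1, 1, 2], dtype=float)
        # hand: centered products sum 2, SSa = 2.75, SSb = 2 -> r^2 = 4/5.5
        assert genetics.ld_r2(a, b) == pytest.approx(8 / 11)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            genetics.ld_r2([1, 1, 1, 1], [0, 1, 2, 1])

    def test_missing_handled_complete_case(self):
        a = np.array([0, 1, 2, 2, np.nan])
        b = np.array([0, 1, 1, 2, 2.0])
        assert genetics.ld_r2(a, b) == pytest.approx(8 / 11)


class TestClump:
    def _ld_toy(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, size=400).astype(float)
        snp2 = np.where(rng.random(400) < 0.55, base, rng.integers(0, 3, 400))
        snp3 = rng.integers(0, 3, size=400).astype(float)
        D = np.column_stack([base, snp2, snp3])
        geno = _toy_genotypes(D, pos=np.array([1_000, 50_000, 120_000]))
        p = pd.Series({"rs0": 1e-8, "rs1": 1e-6, "rs2": 1e-4})
        return geno, p

    def test_uncorrelated_snps_all_retained(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 3, size=(500, 4)).astype(float)
        geno = _toy_genotypes(D)
        p = pd.Series(0.5, index=list(geno.snps))
        assert set(genetics.clump(p, geno)) == set(geno.snps)

    def test_ld_pair_reduced_to_index_snp(self):
        geno, p = self._ld_toy()
        assert genetics.ld_r2(geno.dosages["rs0"], geno.dosages["rs1"]) >= 0.1
        kept = genetics.clump(p, geno)
        assert kept == ["rs0", "rs2"]

    def test_order_invariance(self):
        geno, p = self._ld_toy()
        assert genetics.clump(p.iloc[::-1], geno) == genetics.clump(p, geno)

    def test_window_limits_removal(self):
        geno, p = self._ld_toy()
        kept = genetics.clump(p, geno, window_kb=10)  # rs1 outside 10 kb window
        assert kept == ["rs0", "rs1", "rs2"]


class TestPRS:
    def test_hand_score(self):
        D = np.array([[0.0, 1.0, 2.0]])
        geno = _toy_genotypes(D, pos=np.array([1, 500_000, 1_000_000]))
        wt = genetics.WeightTable(
            pd.DataFrame(
                {"snp": ["rs0", "rs1", "rs2"], "effect_allele": "A",
                 "beta": [0.5, -1.0, 2.0], "p": [1e-4, 1e-4, 1e-4]}
            )
        )
        prof = genetics.prs(geno, wt, clump_first=False)
        assert prof.averaged.iloc[0] == pytest.approx(3.0)

    def test_threshold_grid_has_100_values(self):
        grid = genetics.default_thresholds()
        assert len(grid) == 100
        assert grid[0] == pytest.approx(0.005)
        assert grid[-1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diff(grid), 0.005)

    def test_zero_weights_give_zero_scores(self):
        geno, _ = synth.generate_genotypes(n_subjects=50, n_snps=6, seed=4)
        wt = genetics.WeightTable(
            pd.DataFrame(
                {"snp": list(geno.snps),
                 "effect_allele": geno.snp_info["effect_allele"].to_list(),
                 "beta": 0.0, "p": 0.01}
            )
        )
        prof = genetics.prs(geno, wt)
        assert (prof.averaged == 0).all()

    def test_additivity_in_weights(self):
        geno, _ = synth.generate_genotypes(n_subjects=80, n_snps=6, seed=5)
        rng = np.random.default_rng(6)
        w1 = rng.normal(size=6)
        w2 = rng.normal(size=6)

        def profile(w):
            wt = genetics.WeightTable(
                pd.DataFrame(
                    {"snp": list(geno.snps),
                     "effect_allele": geno.snp_info["effect_allele"].to_list(),
                     "beta": w, "p": 0.01}
                )
            )
            return genetics.prs(geno, wt, clump_first=False).averaged

        np.testing.assert_allclose(
            profile(w1 + w2), profile(w1) + profile(w2), atol=1e-10
        )

    def test_missing_dosage_mean_imputed(self):
        D = np.array([[np.nan], [1.0]])
        geno = _toy_genotypes(D, maf=np.array([0.25]))
        wt = genetics.WeightTable(
            pd.DataFrame({"snp": ["rs0"], "effect_allele": ["A"], "beta": [1.0], "p": [0.001]})
        )
        prof = genetics.prs(geno, wt, clump_first=False)
        assert prof.averaged.iloc[0] == pytest.approx(0.5)  # 2 * MAF

    def test_effect_allele_flip(self):
        D = np.array([[2.0], [0.0]])
        geno = _toy_genotypes(D)  # effect A, other G
        wt_flipped = genetics.WeightTable(
            pd.DataFrame({"snp": ["rs0"], "effect_allele": ["G"], "beta": [1.0], "p": [0.001]})
        )
        prof = genetics.prs(geno, wt_flipped, clump_first=False)
        np.testing.assert_allclose(prof.averaged.to_numpy(), [-2.0, 0.0])


class TestScan:
    def test_beta_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        geno, truth = synth.generate_genotypes(
            n_subjects=300, n_snps=8, causal=[(2, 0.3)], seed=7
        )
        pheno = synth.simulate_phenotype(geno, truth, seed=8)
        cov = pd.DataFrame(
            {"c1": np.random.default_rng(9).normal(size=300)},
            index=geno.dosages.index,
        )
        scan = genetics.gwas_scan(pheno, geno, cov)
        for snp in geno.snps:
            X = sm.add_constant(
                np.column_stack([geno.dosages[snp], cov["c1"]])
            )
            ols = sm.OLS(pheno.to_numpy(), X).fit()
            row = scan.table.set_index("SNP").loc[snp]
            assert row["BETA"] == pytest.approx(ols.params[1], rel=1e-8)
            assert row["SE"] == pytest.approx(ols.bse[1], rel=1e-8)
            assert row["P"] == pytest.approx(ols.pvalues[1], rel=1e-6)

    def test_planted_snp_found_and_clumped(self):
        geno, truth = synth.generate_genotypes(
            n_subjects=2000, n_snps=30, within_block_r=0.7,
            causal=[(5, 0.6)], seed=10,
        )
        pheno = synth.simulate_phenotype(geno, truth, noise_sd=1.0, seed=11)
        scan = genetics.gwas_scan(pheno, geno)
        assert "rs000006" in scan.significant
        # neighbors in LD with the causal SNP must not appear as extra hits
        sigpos = geno.snp_info.loc[scan.significant, "pos"]
        assert len(scan.significant) == len(sigpos.unique())

    def test_output_mirrors_summary_statistic_columns(self):
        geno, _ = synth.generate_genotypes(n_subjects=100, n_snps=5, seed=12)
        pheno = pd.Series(
            np.random.default_rng(13).normal(size=100), index=geno.dosages.index
        )
        scan = genetics.gwas_scan(pheno, geno)
        assert list(scan.table.columns) == ["SNP", "CHR", "BP", "A1", "BETA", "SE", "T", "P"]
        assert scan.lambda_gc > 0
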