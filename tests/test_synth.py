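"""Generator correctness: determinism, planted structure, spatial nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroaging import synth
from neuroaging.exceptions import ConfigurationError
from neuroaging.genetics import ld_r2
from neuroaging.maps import RegionMap


def _noise_free(**kw):
    return synth.adult_config(
        n_subjects=50,
        rel_sigma_b0=0.0,
        rel_sigma_b1=0.0,
        rel_sigma_e=0.0,
        rel_sex_effect=0.0,
        rel_site_effect=0.0,
        rel_handedness_effect=0.0,
        rel_ethnicity_effect=0.0,
        rel_icv_effect=0.0,
        pattern_mixing=0.0,
        seed=0,
        **kw,
    )


class TestCohortGenerator:
    def test_zero_noise_volumes_lie_on_fixed_quadratic(self):
        cfg = _noise_free()
        cohort, _ = synth.generate_longitudinal_cohort(cfg)
        t = cohort.data["age"].to_numpy() - cfg.age_center
        for j, roi in enumerate(cfg.rois[:5]):
            v = cfg.base_volumes[j]
            expected = v * (1 + cfg.decline_rate * t + cfg.curvature * t**2)
            np.testing.assert_allclose(cohort.data[roi].to_numpy(), expected, rtol=1e-12)

    def test_pattern_fraction_within_binomial_bounds(self):
        pi = 0.49
        n = 2000
        cfg = synth.adult_config(n_subjects=n, pattern_mixing=pi, seed=5)
        _, truth = synth.generate_longitudinal_cohort(cfg)
        frac = (truth.labels == 2).mean()
        half = stats.norm.ppf(0.995) * np.sqrt(pi * (1 - pi) / n)
        assert abs(frac - pi) < half

    def test_default_adult_design(self):
        cfg = synth.adult_config(n_subjects=1500, seed=6)
        cohort, _ = synth.generate_longitudinal_cohort(cfg)
        ages = cohort.data["age"]
        assert ages.min() >= 44 and ages.max() <= 82
        fup = cohort.data.groupby("subject_id").size() > 1
        # binomial 99.9% bounds around the configured 10% follow-up share
        half = stats.norm.ppf(0.9995) * np.sqrt(0.1 * 0.9 / 1500)
        assert abs(fup.mean() - 0.10) < half

    def test_same_seed_bit_identical(self):
        cfg = synth.adult_config(n_subjects=80, pattern_mixing=0.3, seed=42)
        c1, t1 = synth.generate_longitudinal_cohort(cfg)
        c2, t2 = synth.generate_longitudinal_cohort(cfg)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        pd.testing.assert_series_equal(t1.labels, t2.labels)
        pd.testing.assert_frame_equal(t1.b0, t2.b0)

    def test_variance_components_recovered_at_scale(self):
        cfg = synth.adult_config(
            n_subjects=5000, rois=("roiA",), base_volumes=np.array([1e4]), seed=9
        )
        _, truth = synth.generate_longitudinal_cohort(cfg)
        sd_b0 = truth.b0["roiA"].std()
        sd_b1 = truth.b1["roiA"].std()
        corr = truth.b0["roiA"].corr(truth.b1["roiA"])
        assert abs(sd_b0**2 / (cfg.rel_sigma_b0 * 1e4) ** 2 - 1) < 0.10
        assert abs(sd_b1**2 / (cfg.rel_sigma_b1 * 1e4) ** 2 - 1) < 0.10
        assert abs(corr - cfg.re_correlation) < 0.05

    @pytest.mark.parametrize(
        "bad",
        [
            {"pattern_mixing": 1.3},
            {"rel_sigma_b0": -0.1},
            {"re_correlation": 1.5},
            {"age_range": (50.0, 50.0)},
            {"visit_count_probs": {1: 0.4, 2: 0.4}},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            synth.adult_config(n_subjects=10, **bad)

    @pytest.mark.parametrize("maker", [synth.adult_config, synth.adolescent_config])
    def test_visit_ages_stay_inside_range(self, maker):
        cfg = maker(n_subjects=400, seed=3)
        cohort, _ = synth.generate_longitudinal_cohort(cfg)
        lo, hi = cfg.age_range
        assert cohort.data["age"].between(lo, hi).all()


class TestParcellation:
    def test_default_gives_66_unit_centroids(self, parcellation):
        assert parcellation.n_cortical == 66
        pts = parcellation.cortical()[["x", "y", "z"]].to_numpy()
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-9)

    def test_left_right_mirror_pairs(self, parcellation):
        left = parcellation.centroids("L")
        right = parcellation.centroids("R")
        np.testing.assert_allclose(right, left * np.array([-1, 1, 1]), atol=1e-12)

    def test_min_separation_matches_exhaustive_check(self):
        parc = synth.generate_parcellation(4, seed=2)
        pts = parc.centroids("L")
        angles = [
            np.arccos(np.clip(pts[i] @ pts[j], -1, 1))
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        assert min(angles) > 0
        # brute-force minimum equals pairwise-matrix minimum
        d = np.arccos(np.clip(pts @ pts.T, -1, 1))
        np.fill_diagonal(d, np.inf)
        assert np.isclose(min(angles), d.min())

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ConfigurationError):
            synth.generate_parcellation(3)


class TestExpression:
    def test_white_noise_limit_uncorrelated_regions(self, parcellation):
        X, _ = synth.generate_expression(parcellation, n_genes=800, smoothness=0.0, seed=1)
        c = np.corrcoef(X.to_numpy())
        off = c[np.triu_indices_from(c, k=1)]
        assert abs(off.mean()) < 0.01

    def test_perfect_coupling_reproduces_map(self, parcellation):
        rois = parcellation.cortical_rois()
        target = RegionMap(pd.Series(np.sin(np.arange(len(rois))), index=rois))
        X, truth = synth.generate_expression(
            parcellation, n_genes=20, coupled_map=target, n_coupled=1,
            coupling_r=1.0, seed=2,
        )
        g = truth.coupled_genes[0]
        z = target.standardize().values
        np.testing.assert_allclose(X[g].to_numpy(), z.to_numpy(), atol=1e-12)

    def test_smooth_genes_beat_shuffled_morans_i(self, parcellation):
        pts = parcellation.cortical()[["x", "y", "z"]].to_numpy()
        d = np.arccos(np.clip(pts @ pts.T, -1, 1))
        W = np.exp(-d) - np.eye(len(d))

        def morans(v):
            v = v - v.mean()
            return len(v) / W.sum() * (v @ W @ v) / (v @ v)

        X, _ = synth.generate_expression(parcellation, n_genes=100, smoothness=0.6, seed=3)
        rng = np.random.default_rng(4)
        wins = 0
        for j in range(100):
            g = X.iloc[:, j].to_numpy()
            if morans(g) > morans(rng.permutation(g)):
                wins += 1
        assert wins >= 95

    def test_coupled_exceeding_total_rejected(self, parcellation):
        with pytest.raises(ConfigurationError):
            synth.generate_expression(parcellation, n_genes=5, n_coupled=6)


class TestGenotypes:
    def test_dosages_domain_and_positions(self):
        geno, _ = synth.generate_genotypes(n_subjects=200, n_snps=40, seed=1)
        assert set(np.unique(geno.dosages.to_numpy())) <= {0.0, 1.0, 2.0}
        assert geno.snp_info["pos"].is_monotonic_increasing

    def test_fixed_maf_within_binomial_bounds(self):
        geno, _ = synth.generate_genotypes(
            n_subjects=3000, n_snps=30, within_block_r=0.0,
            maf_range=(0.3, 0.3), seed=2,
        )
        freqs = geno.dosages.mean(axis=0) / 2
        half = stats.norm.ppf(0.9999) * np.sqrt(0.3 * 0.7 / (2 * 3000))
        assert (np.abs(freqs - 0.3) < half).mean() > 0.9

    def test_independent_snps_have_null_level_r2(self):
        n = 400
        geno, _ = synth.generate_genotypes(
            n_subjects=n, n_snps=60, within_block_r=0.0, seed=3
        )
        D = geno.dosages.to_numpy()
        c = np.corrcoef(D.T) ** 2
        off = c[np.triu_indices_from(c, k=1)]
        # E[r^2] = 1/n under independence
        assert abs(off.mean() - 1 / n) < 3 / n

    def test_duplicated_snp_column_r2_is_one(self):
        geno, _ = synth.generate_genotypes(n_subjects=100, n_snps=5, seed=4)
        col = geno.dosages.iloc[:, 0]
        assert ld_r2(col, col.copy()) == pytest.approx(1.0)

    def test_block_neighbors_show_ld(self):
        geno, _ = synth.generate_genotypes(
            n_subjects=2000, n_snps=40, block_size=10, within_block_r=0.8, seed=5
        )
        D = geno.dosages.to_numpy()
        within = [ld_r2(D[:, j], D[:, j + 1]) for j in range(0, 9)]
        across = [ld_r2(D[:, 9], D[:, 10])]
        # dosage LD is attenuated relative to the latent AR(1) correlation,
        # but same-block neighbors must far exceed the cross-block null
        assert np.mean(within) > 0.15
        assert np.mean(within) > 20 * max(across[0], 1e-3)
        assert across[0] < 0.05

    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigurationError):
            synth.generate_genotypes(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigurationError):
            synth.generate_genotypes(within_block_r=1.0)

    def test_vcf_read_back_by_independent_parser(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        geno, _ = synth.generate_genotypes(n_subjects=20, n_snps=6, seed=8)
        path = tmp_path / "g.vcf"
        geno.to_vcf(path)
        recs = list(cyvcf2.VCF(str(path)))
        assert [r.ID for r in recs] == list(geno.snps)
        ds = np.array([r.format("DS").ravel() for r in recs]).T
        np.testing.assert_allclose(ds, geno.dosages.to_numpy(), atol=1e-3)

    def test_dosage_tsv_roundtrip(self, tmp_path):
        geno, _ = synth.generate_genotypes(n_subjects=15, n_snps=4, seed=9)
        path = tmp_path / "d.tsv"
        geno.to_dosage_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col="subject_id")
        pd.testing.assert_frame_equal(back, geno.dosages)


class TestMirroredPair:
    def test_planted_profiles_have_opposite_ranking(self):
        dev, age, truth = synth.generate_mirrored_cohorts(
            n_dev=50, n_age=50, seed=2
        )
        rho = stats.spearmanr(truth["dev_apc"], truth["age_apc"]).statistic
        assert rho < -0.5
        for roi in truth["lifo_rois"]:
            assert truth["dev_apc"][roi] > truth["dev_apc"].median()
            assert truth["age_apc"][roi] < truth["age_apc"].median()
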