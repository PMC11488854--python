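"""End-to-end validation benchmarks on synthetic data.

Each routine regenerates its inputs from a seed, runs the package's
analysis path, and returns the measured quantities (recovery scores,
calibration rates, oracle gaps).  They back both the validation test
suite and the reproduction script, and double as worked examples of the
full pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import contrasts, genetics, mirroring, patterns, pls, synth, trajectory
from .maps import RegionMap, ZMap

__all__ = [
    "blup_oracle_gap",
    "pattern_recovery",
    "deviation_phenotype_recovery",
    "spin_calibration",
    "pls_oracle",
    "apc_and_mirroring_exact",
    "effect_size_hand_checks",
    "prs_hand_checks",
    "scan_calibration_and_power",
    "mirroring_recovery",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ----------------------------------------------------------------------
def blup_oracle_gap(seed: int = 0) -> float:
    """Max |BLUP - dense GLS closed form| on a 3-subject toy with the
    variance components held fixed (not estimated)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    G = np.array([[4.0, 0.5], [0.5, 1.0]])
    sigma2 = 2.0
    rows = []
    for i, s in enumerate("ABC"):
        b = rng.multivariate_normal([0, 0], G)
        for v, t in enumerate([-1.0, 0.0, 1.0]):
            y = 10 + 2 * t - 0.5 * t**2 + b[0] + b[1] * t + rng.normal(0, np.sqrt(sigma2))
            rows.append({"subject_id": s, "visit": v, "age": 60 + 10 * t,
                         "sex": 0, "site": 0, "handedness": 0, "ethnicity": 0,
                         "icv": 1.5e6, "tgmv": y, "roi_a": y})
    d = pd.DataFrame(rows)
    d["age_c"] = (d["age"] - 60.0) / 10.0
    d["age_c2"] = d["age_c"] ** 2

    from statsmodels.regression.mixed_linear_model import MixedLM

    model = MixedLM.from_formula(
        "roi_a ~ age_c + age_c2", data=d, groups=d["subject_id"], re_formula="~age_c"
    )
    est = trajectory.ROITrajectoryLMM(roi="roi_a", covariates=())
    est.age_mean_ = 60.0
    est.random_slope = True
    est._model = model
    blups = est.blups_at(G, sigma2).to_numpy()

    # independent dense-matrix oracle: full V, no per-subject blocking
    y = np.asarray(model.endog)
    X = model.exog
    Z = model.exog_re
    groups = np.asarray(model.groups)
    uniq = list(pd.unique(groups))
    Zfull = np.zeros((len(y), 2 * len(uniq)))
    for j, g in enumerate(uniq):
        idx = np.flatnonzero(groups == g)
        Zfull[idx, 2 * j : 2 * j + 2] = Z[idx]
    Gfull = np.kron(np.eye(len(uniq)), G)
    V = Zfull @ Gfull @ Zfull.T + sigma2 * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    oracle = (Gfull @ Zfull.T @ Vinv @ (y - X @ beta)).reshape(len(uniq), 2)
    return float(np.abs(blups - oracle).max())


# ----------------------------------------------------------------------
def pattern_recovery(seed: int = 0, n_subjects: int = 2000) -> dict:
    """Recover two planted aging patterns from the full trajectory ->
    deviation -> PCA -> k-means path."""
    cfg = synth.adult_config(n_subjects=n_subjects, pattern_mixing=0.5, seed=seed)
    cohort, truth = synth.generate_longitudinal_cohort(cfg)
    dev, _ = trajectory.fit_deviation_matrix(cohort, reference_age=60.0)
    model = patterns.PatternClusterer(n_components=15, k=2, seed=0).fit(
        dev, cohort=cohort
    )
    labels = model.labels_
    ari = float(adjusted_rand_score(truth.labels.reindex(labels.index), labels))
    base = cohort.baseline().set_index("subject_id")["tgmv"]
    means = base.groupby(labels).mean()
    return {
        "ari": ari,
        "pattern1_share": float((labels == 1).mean()),
        "labeling_convention_ok": bool(means.loc[1] > means.loc[2]),
        "n": n_subjects,
    }


# ----------------------------------------------------------------------
def deviation_phenotype_recovery(seed: int = 0, n_subjects: int = 1000) -> dict:
    """Correlation of the estimated and true total-volume deviation at 60 y
    (cohort with >= 30% two-visit subjects)."""
    cfg = synth.adult_config(
        n_subjects=n_subjects,
        visit_count_probs={1: 0.7, 2: 0.3},
        pattern_mixing=0.5,
        seed=seed,
    )
    cohort, truth = synth.generate_longitudinal_cohort(cfg)
    m = trajectory.ROITrajectoryLMM(roi="tgmv").fit(cohort)
    est = m.deviation_at_age(60.0)
    true = truth.total_deviation(60.0).reindex(est.index)
    phen = trajectory.estimate_total_gmv_at_age(m, 60.0)
    return {
        "deviation_correlation": float(np.corrcoef(est, true)[0, 1]),
        "phenotype_correlation": float(np.corrcoef(phen.reindex(true.index), true)[0, 1]),
        "n": n_subjects,
    }


# ----------------------------------------------------------------------
def spin_calibration(
    seed: int = 0, n_runs: int = 500, n_perm: int = 200, alpha: float = 0.05
) -> dict:
    """Empirical rejection rate of the spin test for independent
    white-noise maps on the default 33-per-hemisphere parcellation."""
    parc = synth.generate_parcellation(33, seed=seed)
    seeds = _child_seeds(seed, 2 * n_runs)
    rejections = 0
    n_rois = parc.n_cortical
    rois = None
    for r in range(n_runs):
        rng = np.random.default_rng(seeds[2 * r])
        spin = pls.generate_spin_permutations(parc, n_perm=n_perm, seed=seeds[2 * r + 1])
        if rois is None:
            rois = spin.rois
        y1 = rng.normal(size=n_rois)
        y2 = pd.Series(rng.normal(size=n_rois), index=rois)
        obs = stats.spearmanr(y1, y2.to_numpy()).statistic

        def stat(y_perm, y1=y1):
            return stats.spearmanr(y1, y_perm).statistic

        p = pls.spin_pvalue(obs, stat, y2, spin)
        rejections += p <= alpha
    return {"rejection_rate": rejections / n_runs, "n": n_runs}


# ----------------------------------------------------------------------
def pls_oracle(seed: int = 0) -> dict:
    """Explained variance vs an independent regression R^2, plus the exact
    perfect-predictor construction."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parc = synth.generate_parcellation(33, seed=seed)
    rois = parc.cortical_rois()
    target = RegionMap(pd.Series(rng.normal(size=len(rois)), index=rois))
    X, _ = synth.generate_expression(
        parc, n_genes=200, smoothness=0.5, coupled_map=target, n_coupled=5,
        coupling_r=0.8, seed=seed,
    )
    fit = pls.fit_pls1(X, target.standardize())
    t = fit.scores_.to_numpy()
    yv = target.standardize().values.reindex(fit.scores_.index).to_numpy()
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ coef
    r2 = 1 - resid @ resid / ((yv - yv.mean()) @ (yv - yv.mean()))

    # perfect predictor: one gene equals the map, others orthogonal in-sample
    y = rng.normal(size=40)
    y = (y - y.mean()) / y.std(ddof=1)
    cols = {}
    for j in range(10):
        g = rng.normal(size=40)
        g = g - g.mean()
        cols[f"g{j}"] = g - y * (g @ y) / (y @ y)
    cols["target"] = y
    fit2 = pls.fit_pls1(pd.DataFrame(cols), pd.Series(y))
    return {
        "ev": fit.explained_variance_,
        "ev_r2_gap": float(abs(fit.explained_variance_ - r2)),
        "ev_perfect_predictor": fit2.explained_variance_,
        "n": len(rois),
    }


# ----------------------------------------------------------------------
def apc_and_mirroring_exact() -> dict:
    """Hand-checkable APC value and mirroring antisymmetry gap."""
    rows = []
    for v, (vol, age) in enumerate([(100.0, 50.0), (94.0, 53.0)]):
        rows.append({"subject_id": "A", "visit": v, "age": age,
                     "sex": 0, "site": 0, "handedness": 0, "ethnicity": 0,
                     "icv": 1.5e6, "tgmv": vol, "roiA": vol})
    from .cohort import Cohort

    cohort = Cohort(pd.DataFrame(rows), ("roiA",))
    apc = float(mirroring.compute_subject_apc(cohort, "roiA").loc[0, "apc"])

    rng = np.random.default_rng(0)
    rois = [f"r{i}" for i in range(10)]
    zd = ZMap(pd.Series(rng.normal(size=10), index=rois))
    za = ZMap(pd.Series(rng.normal(size=10), index=rois))
    ab = mirroring.mirroring_scores(zd, za).scores
    ba = mirroring.mirroring_scores(za, zd).scores
    gap = float(np.abs(ab.to_numpy() + ba.reindex(ab.index).to_numpy()).max())
    return {"apc_percent_per_year": apc, "antisymmetry_gap": gap}


# ----------------------------------------------------------------------
def effect_size_hand_checks() -> dict:
    d, _ = contrasts.cohens_d([1, 2, 3], [2, 3, 4])
    orr, _ = contrasts.odds_ratio([[10, 20], [20, 10]])
    bh = contrasts.adjust_pvalues([0.01, 0.02, 0.03], "fdr_bh")
    return {
        "cohens_d": float(d),
        "odds_ratio": float(orr),
        "bh_adjusted_max_gap": float(np.abs(bh - 0.03).max()),
    }


# ----------------------------------------------------------------------
def prs_hand_checks(seed: int = 0) -> dict:
    from .synth.genotypes import GenotypeSet

    info = pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3"],
            "chrom": 1,
            "pos": [1_000, 600_000, 1_200_000],
            "effect_allele": "A",
            "other_allele": "G",
            "maf": [0.25, 0.25, 0.25],
            "call_rate": 1.0,
            "info": 0.99,
        }
    )
    dos = pd.DataFrame(
        [[0.0, 1.0, 2.0]], index=pd.Index(["S0"], name="subject_id"),
        columns=["rs1", "rs2", "rs3"],
    )
    geno = GenotypeSet(dos, info)
    wt = genetics.WeightTable(
        pd.DataFrame({"snp": ["rs1", "rs2", "rs3"], "effect_allele": "A",
                      "beta": [0.5, -1.0, 2.0], "p": [1e-4, 1e-4, 1e-4]})
    )
    profile = genetics.prs(geno, wt, clump_first=False)

    # clumping toy: SNP2 in LD with SNP1, SNP3 independent
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 3, size=500).astype(float)
    snp2 = np.where(rng.random(500) < 0.5, base, rng.integers(0, 3, 500))
    snp3 = rng.integers(0, 3, size=500).astype(float)
    dos2 = pd.DataFrame(
        np.column_stack([base, snp2, snp3]),
        index=pd.Index([f"S{i}" for i in range(500)], name="subject_id"),
        columns=["rs1", "rs2", "rs3"],
    )
    info2 = info.copy()
    info2["pos"] = [1_000, 50_000, 120_000]
    geno2 = GenotypeSet(dos2, info2)
    pvals = pd.Series({"rs1": 1e-8, "rs2": 1e-6, "rs3": 1e-4})
    kept = genetics.clump(pvals, geno2)
    # exhaustive oracle over the 3 SNPs
    brute = []
    removed = set()
    for s in pvals.sort_values().index:
        if s in removed:
            continue
        brute.append(s)
        for t in pvals.index:
            if t not in brute and abs(
                int(info2.set_index("snp").at[s, "pos"]) - int(info2.set_index("snp").at[t, "pos"])
            ) <= 250_000 and genetics.ld_r2(dos2[s], dos2[t]) >= 0.1:
                removed.add(t)
    return {
        "score": float(profile.averaged.iloc[0]),
        "n_thresholds": int(len(profile.thresholds)),
        "clump_matches_bruteforce": bool(kept == brute),
        "n_index_snps": len(kept),
    }


# ----------------------------------------------------------------------
def scan_calibration_and_power(
    seed: int = 0,
    n_null_snps: int = 5000,
    n_subjects: int = 2000,
    n_reps: int = 100,
    beta: float = 0.5,
    maf: float = 0.3,
) -> dict:
    """Null genomic-control lambda and power for a planted common variant.

    The planted effect is ``beta`` phenotype-noise SDs per allele; the
    analytic benchmark is the normal-approximation power at 5e-8 with
    noncentrality beta * sqrt(2 maf (1-maf) n) / sigma.
    """
    s_null, s_pow = _child_seeds(seed, 2)
    geno, _ = synth.generate_genotypes(
        n_subjects=n_subjects, n_snps=n_null_snps, block_size=10,
        within_block_r=0.4, seed=s_null,
    )
    rng = np.random.default_rng(s_null)
    pheno = pd.Series(rng.normal(size=n_subjects), index=geno.dosages.index)
    cov = pd.DataFrame(
        {"sex": rng.integers(0, 2, n_subjects), "age": rng.uniform(44, 82, n_subjects)},
        index=geno.dosages.index,
    )
    scan = genetics.gwas_scan(pheno, geno, cov)
    type1 = float((scan.table["P"] < 0.01).mean())

    rng = np.random.default_rng(s_pow)
    hits = 0
    for _ in range(n_reps):
        dosage = rng.binomial(2, maf, size=n_subjects).astype(float)
        y = beta * dosage + rng.normal(size=n_subjects)
        from .synth.genotypes import GenotypeSet

        info = pd.DataFrame(
            {"snp": ["rs1"], "chrom": 1, "pos": [1000], "effect_allele": "A",
             "other_allele": "G", "maf": [maf], "call_rate": 1.0, "info": 0.99}
        )
        g1 = GenotypeSet(
            pd.DataFrame(dosage[:, None], columns=["rs1"],
                         index=pd.Index([f"S{i}" for i in range(n_subjects)], name="subject_id")),
            info,
        )
        res = genetics.gwas_scan(
            pd.Series(y, index=g1.dosages.index), g1, clump_significant=False
        )
        hits += bool(res.significant)
    ncp = beta * np.sqrt(2 * maf * (1 - maf) * n_subjects)
    z_crit = stats.norm.isf(2.5e-8)
    analytic_power = float(stats.norm.sf(z_crit - ncp) + stats.norm.cdf(-z_crit - ncp))
    return {
        "lambda_gc": scan.lambda_gc,
        "type1_at_0.01": type1,
        "power": hits / n_reps,
        "analytic_power": analytic_power,
        "n": n_null_snps,
    }


# ----------------------------------------------------------------------
def mirroring_recovery(
    seed: int = 0, n_reps: int = 100, n_dev: int = 350, n_age: int = 250
) -> dict:
    """Rate of recovering planted last-in-first-out regions (top-3 by
    mirroring score) and of negative development-aging coupling.

    The development cohort is the larger one because the age-15 evaluation
    point sits near the lower edge of its scan-pair midpoint ages, where
    curve uncertainty is largest.
    """
    seeds = _child_seeds(seed, n_reps)
    neg, top3, rhos = 0, 0, []
    lam_grid = np.logspace(-3, 4, 5)
    for s in seeds:
        dev_c, age_c, truth = synth.generate_mirrored_cohorts(
            n_dev=n_dev, n_age=n_age, seed=s
        )
        res = mirroring.mirroring_pipeline(
            dev_c, age_c, lam_grid=lam_grid, cv_folds=4
        )
        rhos.append(res.spearman)
        neg += res.spearman < 0
        got = set(res.scores.sort_values(ascending=False).head(3).index)
        top3 += got == set(truth["lifo_rois"])
    return {
        "negative_spearman_rate": neg / n_reps,
        "top3_recovery_rate": top3 / n_reps,
        "mean_spearman": float(np.mean(rhos)),
        "n": n_reps,
    }
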