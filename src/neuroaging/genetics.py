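"""Variant QC, LD clumping, polygenic scoring and a covariate-adjusted
per-SNP association scan for the individualized imaging phenotype.

The polygenic risk score follows the clump-then-threshold recipe: weights
are LD-clumped (greedy by ascending p, removing neighbors with r^2 above
threshold inside a base-pair window), scores are computed at every p-value
threshold of the grid 0.005, 0.010, ..., 0.500 (100 thresholds) and
averaged.  The association scan is per-SNP ordinary least squares of the
phenotype on dosage plus covariates, with genomic-control lambda
(median chi^2 / 0.4549) and a genome-wide significant set (p < 5e-8)
reduced to independent index SNPs by the same clumping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError
from .synth.genotypes import GenotypeSet

__all__ = [
    "WeightTable",
    "PRSProfile",
    "ScanResult",
    "variant_qc",
    "ld_r2",
    "clump",
    "prs",
    "gwas_scan",
    "default_thresholds",
]

GENOME_WIDE_P = 5e-8
_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class WeightTable:
    """External summary statistics: SNP -> (effect allele, beta, p)."""

    table: pd.DataFrame  # columns: snp, effect_allele, beta, p

    def __post_init__(self) -> None:
        req = {"snp", "effect_allele", "beta", "p"}
        if not req <= set(self.table.columns):
            raise ValueError(f"weight table needs columns {sorted(req)}")
        p = self.table["p"].to_numpy(dtype=float)
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("weight p-values must lie in (0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "WeightTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class PRSProfile:
    scores: pd.DataFrame       # subjects x thresholds
    averaged: pd.Series        # subjects
    thresholds: np.ndarray
    n_snps_per_threshold: pd.Series
    warnings: list[str] = field(default_factory=list)


@dataclass
class ScanResult:
    table: pd.DataFrame        # SNP, CHR, BP, A1, BETA, SE, T, P
    covariates: tuple[str, ...]
    lambda_gc: float
    significant: list[str]     # clumped genome-wide significant index SNPs
    skipped: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_thresholds() -> np.ndarray:
    """The 100-value grid 0.005 to 0.5 in steps of 0.005."""
    return np.round(np.arange(1, 101) * 0.005, 10)


def variant_qc(
    genotypes: GenotypeSet,
    max_missing: float = 0.05,
    min_maf: float = 0.005,
    min_info: float = 0.8,
) -> tuple[GenotypeSet, dict[str, int]]:
    """Drop SNPs failing call-rate, MAF or imputation-INFO rules."""
    info = genotypes.snp_info
    call_rate = 1.0 - genotypes.dosages.isna().mean(axis=0)
    fail_missing = call_rate < 1.0 - max_missing
    fail_maf = info["maf"] < min_maf
    fail_info = info["info"] < min_info
    counts = {
        "call_rate": int(fail_missing.sum()),
        "maf": int(fail_maf.sum()),
        "info": int(fail_info.sum()),
    }
    keep = ~(fail_missing.to_numpy() | fail_maf.to_numpy() | fail_info.to_numpy())
    kept = list(info.index[keep])
    return genotypes.subset(kept), counts


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors (complete cases)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete dosage pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("zero-variance dosage vector")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump(
    pvalues: pd.Series,
    genotypes: GenotypeSet,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping: ascending p, ties broken by position.

    Retains an index SNP, removes all not-yet-retained SNPs within
    ``window_kb`` of it whose r^2 with it meets the threshold.  The result
    is invariant to input SNP order.
    """
    info = genotypes.snp_info
    snps = [s for s in pvalues.index if s in info.index]
    order = sorted(snps, key=lambda s: (float(pvalues[s]), int(info.at[s, "pos"]), s))
    removed: set[str] = set()
    index_snps: list[str] = []
    window = window_kb * 1000.0
    for s in order:
        if s in removed:
            continue
        index_snps.append(s)
        chrom, pos = info.at[s, "chrom"], info.at[s, "pos"]
        near = info.index[
            (info["chrom"] == chrom) & (np.abs(info["pos"] - pos) <= window)
        ]
        for t in near:
            if t == s or t in removed or t in index_snps or t not in set(snps):
                continue
            try:
                r2 = ld_r2(genotypes.dosages[s], genotypes.dosages[t])
            except DegenerateInputError:
                continue
            if r2 >= r2_threshold:
                removed.add(t)
    return index_snps


def _aligned_weights(genotypes: GenotypeSet, weights: WeightTable):
    """Match weights to panel SNPs, flipping beta when the stated effect
    allele is the panel's other (reference) allele; strand-ambiguous
    (A/T, C/G) SNPs are dropped."""
    info = genotypes.snp_info
    wt = weights.table.set_index("snp")
    aligned = {}
    n_ambiguous = 0
    for snp in wt.index:
        if snp not in info.index:
            continue
        ea, oa = info.at[snp, "effect_allele"], info.at[snp, "other_allele"]
        if (ea, oa) in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        beta = float(wt.at[snp, "beta"])
        stated = wt.at[snp, "effect_allele"] if "effect_allele" in wt.columns else ea
        if stated == oa:
            beta = -beta
        elif stated != ea:
            continue  # allele mismatch, unscorable
        aligned[snp] = (beta, float(wt.at[snp, "p"]))
    return aligned, n_ambiguous


def prs(
    genotypes: GenotypeSet,
    weights: WeightTable,
    thresholds: np.ndarray | None = None,
    clump_first: bool = True,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    include_p1: bool = False,
) -> PRSProfile:
    """Multi-threshold polygenic score, averaged over the grid.

    Pipeline order: clump -> threshold -> score.  Missing dosages are
    imputed as twice the effect-allele frequency (the PRS convention).
    """
    if thresholds is None:
        thresholds = default_thresholds()
        if include_p1:
            thresholds = np.append(thresholds, 1.0)
    thresholds = np.asarray(thresholds, dtype=float)

    aligned, _ = _aligned_weights(genotypes, weights)
    warn: list[str] = []
    if clump_first and aligned:
        p_series = pd.Series({s: p for s, (_, p) in aligned.items()})
        kept = clump(p_series, genotypes, r2_threshold, window_kb)
        aligned = {s: aligned[s] for s in kept}

    subjects = genotypes.dosages.index
    snps = list(aligned)
    if not snps:
        warn.append("no weight SNP present in the genotype panel")
        zeros = pd.DataFrame(0.0, index=subjects, columns=[f"p<{t:g}" for t in thresholds])
        return PRSProfile(zeros, zeros.mean(axis=1), thresholds,
                          pd.Series(0, index=zeros.columns), warn)

    D = genotypes.dosages[snps].to_numpy(dtype=float)
    freq = genotypes.snp_info.loc[snps, "maf"].to_numpy(dtype=float)
    fill = 2.0 * freq
    nanmask = np.isnan(D)
    if nanmask.any():
        D = np.where(nanmask, fill[None, :], D)
    betas = np.array([aligned[s][0] for s in snps])
    ps = np.array([aligned[s][1] for s in snps])

    cols, counts = {}, {}
    for t in thresholds:
        sel = ps <= t
        name = f"p<{t:g}"
        cols[name] = D[:, sel] @ betas[sel]
        counts[name] = int(sel.sum())
    if counts[f"p<{thresholds.min():g}"] == 0:
        warn.append("no SNP passes the smallest threshold; score is 0 there")
    scores = pd.DataFrame(cols, index=subjects)
    return PRSProfile(
        scores=scores,
        averaged=scores.mean(axis=1).rename("prs_avg"),
        thresholds=thresholds,
        n_snps_per_threshold=pd.Series(counts),
        warnings=warn,
    )


def gwas_scan(
    phenotype: pd.Series,
    genotypes: GenotypeSet,
    covariates: pd.DataFrame | None = None,
    sig_threshold: float = GENOME_WIDE_P,
    clump_significant: bool = True,
) -> ScanResult:
    """Per-SNP OLS of phenotype on dosage plus covariates.

    Covariates are projected out of both phenotype and dosages once
    (Frisch-Waugh), so each SNP costs one inner product.  Missing dosages
    are mean-imputed per SNP before projection.
    """
    subjects = genotypes.dosages.index
    y = phenotype.reindex(subjects).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some genotyped subjects")
    n = len(y)
    if covariates is not None:
        C = pd.get_dummies(covariates.reindex(subjects), drop_first=True, dtype=float)
        X0 = np.column_stack([np.ones(n), C.to_numpy(dtype=float)])
        cov_names = tuple(C.columns)
    else:
        X0 = np.ones((n, 1))
        cov_names = ()
    q, _ = np.linalg.qr(X0)
    k0 = X0.shape[1]

    y_res = y - q @ (q.T @ y)
    D = genotypes.dosages.to_numpy(dtype=float)
    colmean = np.nanmean(D, axis=0)
    nanmask = np.isnan(D)
    if nanmask.any():
        D = np.where(nanmask, colmean[None, :], D)
    D_res = D - q @ (q.T @ D)

    dof = n - k0 - 1
    ss_d = (D_res**2).sum(axis=0)
    skipped = [s for s, v in zip(genotypes.snps, ss_d) if v <= 1e-12]
    ok = ss_d > 1e-12
    beta = np.full(D.shape[1], np.nan)
    se = np.full(D.shape[1], np.nan)
    beta[ok] = (D_res[:, ok] * y_res[:, None]).sum(axis=0) / ss_d[ok]
    resid_ss = (y_res**2).sum() - beta[ok] ** 2 * ss_d[ok]
    sigma2 = resid_ss / dof
    se[ok] = np.sqrt(sigma2 / ss_d[ok])
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    info = genotypes.snp_info
    table = pd.DataFrame(
        {
            "SNP": list(genotypes.snps),
            "CHR": info["chrom"].to_numpy(),
            "BP": info["pos"].to_numpy(),
            "A1": info["effect_allele"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "T": tval,
            "P": pval,
        }
    )
    chi2 = tval[np.isfinite(tval)] ** 2
    lam = float(np.median(chi2) / _CHI2_MEDIAN_1DF) if len(chi2) else np.nan

    sig = table.loc[table["P"] < sig_threshold, ["SNP", "P"]]
    if clump_significant and len(sig):
        significant = clump(
            sig.set_index("SNP")["P"], genotypes, r2_threshold=0.1, window_kb=250.0
        )
    else:
        significant = sig["SNP"].tolist()
    return ScanResult(
        table=table,
        covariates=cov_names,
        lambda_gc=lam,
        significant=significant,
        skipped=skipped,
    )
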