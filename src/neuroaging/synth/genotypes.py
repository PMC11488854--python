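"""Synthetic LD-block genotypes with planted phenotype effects.

Dosages are produced by thresholding a latent Gaussian that follows an
AR(1) process within blocks (two independent haplotypes per subject), so
adjacent same-block SNPs show tunable linkage disequilibrium while blocks
are mutually independent - a simple, analytically checkable stand-in for
imputed genotype panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..exceptions import ConfigurationError

__all__ = ["GenotypeSet", "GenotypeTruth", "generate_genotypes", "simulate_phenotype"]

_ALLELES = ("A", "C", "G", "T")


@dataclass
class GenotypeSet:
    """Subject x SNP dosage matrix plus per-SNP metadata.

    ``snp_info`` columns: snp, chrom, pos, effect_allele, other_allele,
    maf, call_rate, info.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        info = self.snp_info.set_index("snp") if "snp" in self.snp_info.columns else self.snp_info
        self.snp_info = info
        for chrom, grp in self.snp_info.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ConfigurationError(
                    f"positions must be non-decreasing within chromosome {chrom}"
                )

    @property
    def snps(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_subjects(self) -> int:
        return len(self.dosages)

    def subset(self, snps) -> "GenotypeSet":
        snps = list(snps)
        return GenotypeSet(self.dosages[snps].copy(), self.snp_info.loc[snps].reset_index())

    def to_dosage_tsv(self, path) -> None:
        self.dosages.rename_axis("subject_id").to_csv(path, sep="\t")

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT and DS fields."""
        subjects = list(self.dosages.index)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(self.snp_info["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                '##INFO=<ID=INFO_SCORE,Number=1,Type=Float,'
                'Description="Imputation INFO score">\n'
            )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(subjects)
                + "\n"
            )
            gts = {0: "0/0", 1: "0/1", 2: "1/1"}
            for snp in self.snps:
                meta = self.snp_info.loc[snp]
                calls = []
                for d in self.dosages[snp]:
                    if np.isnan(d):
                        calls.append("./.:.")
                    else:
                        calls.append(f"{gts[int(round(d))]}:{d:.3f}")
                fh.write(
                    f"{meta['chrom']}\t{int(meta['pos'])}\t{snp}\t"
                    f"{meta['other_allele']}\t{meta['effect_allele']}\t.\tPASS\t"
                    f"INFO_SCORE={meta['info']:.4f}\tGT:DS\t" + "\t".join(calls) + "\n"
                )


@dataclass
class GenotypeTruth:
    causal_effects: dict[str, float] = field(default_factory=dict)


def generate_genotypes(
    n_subjects: int = 2000,
    n_snps: int = 100,
    block_size: int = 10,
    within_block_r: float = 0.6,
    maf_range: tuple[float, float] = (0.05, 0.5),
    causal: list[tuple[int | str, float]] | None = None,
    seed: int = 0,
    chrom: int = 1,
    mean_spacing_bp: int = 10_000,
) -> tuple[GenotypeSet, GenotypeTruth]:
    """Generate dosages in {0,1,2} with AR(1) within-block LD."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie in (0, 0.5]")
    if not abs(within_block_r) < 1:
        raise ConfigurationError("|within_block_r| must be < 1")
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    mafs = rng.uniform(lo, hi, size=n_snps)
    thresholds = stats.norm.ppf(1 - mafs)

    # two latent haplotypes per subject, AR(1) within each block
    latent = np.empty((2, n_subjects, n_snps))
    r = within_block_r
    innov_sd = np.sqrt(1 - r**2)
    eps = rng.standard_normal((2, n_subjects, n_snps))
    for j in range(n_snps):
        if j % block_size == 0:
            latent[:, :, j] = eps[:, :, j]
        else:
            latent[:, :, j] = r * latent[:, :, j - 1] + innov_sd * eps[:, :, j]
    alleles = (latent > thresholds[None, None, :]).astype(np.int8)
    dosage = alleles.sum(axis=0).astype(float)

    positions = np.cumsum(rng.integers(1, 2 * mean_spacing_bp, size=n_snps))
    snp_ids = [f"rs{j + 1:06d}" for j in range(n_snps)]
    pair_idx = rng.integers(0, len(_ALLELES), size=(n_snps, 2)) % 4
    eff = [_ALLELES[(a + 1) % 4] if a == b else _ALLELES[b] for a, b in pair_idx]
    oth = [_ALLELES[a] for a, b in pair_idx]
    info = rng.uniform(0.85, 1.0, size=n_snps)

    emp_freq = dosage.mean(axis=0) / 2.0
    emp_maf = np.minimum(emp_freq, 1 - emp_freq)
    snp_info = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chrom,
            "pos": positions,
            "effect_allele": eff,
            "other_allele": oth,
            "maf": emp_maf,
            "call_rate": 1.0,
            "info": info,
        }
    )
    subjects = pd.Index([f"S{i:06d}" for i in range(n_subjects)], name="subject_id")
    dosages = pd.DataFrame(dosage, index=subjects, columns=snp_ids)

    truth = GenotypeTruth()
    for snp, effect in causal or []:
        name = snp_ids[snp] if isinstance(snp, (int, np.integer)) else str(snp)
        truth.causal_effects[name] = float(effect)
    return GenotypeSet(dosages, snp_info), truth


def simulate_phenotype(
    genotypes: GenotypeSet,
    truth: GenotypeTruth,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Phenotype = sum of planted per-allele effects + Gaussian noise."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = rng.normal(0.0, noise_sd, size=genotypes.n_subjects)
    for snp, effect in truth.causal_effects.items():
        y = y + effect * genotypes.dosages[snp].to_numpy()
    return pd.Series(y, index=genotypes.dosages.index, name="phenotype")
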