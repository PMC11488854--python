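# neuroaging

Population clustering of longitudinal structural brain aging, its
"last in, first out" mirroring of brain development, and the coupling of
both to regional gene expression and common genetic variation — as a
tested, reusable Python pipeline exercised end-to-end on synthetic
cohorts with known ground truth.

## Who this is for

Researchers modeling longitudinal MRI-derived volumes (one scan for most
subjects, a follow-up for some) who want: per-subject trajectory
deviations from a mixed model, data-driven aging subtypes, smooth
volume–age rate curves, development–aging mirroring maps, spin-test
imaging-transcriptomics, and polygenic scoring / a per-SNP association
scan for an individualized imaging phenotype — with every stage unit- and
recovery-tested against oracles on synthetic data.

## The models in brief

**Trajectories.** Per ROI, volume follows a mixed model with fixed
quadratic age effects and per-subject random intercept and age slope,

&nbsp;&nbsp;V_i(t) = β₀ + β₁s + β₂s² + γ'xᵢ + b₀ᵢ + b₁ᵢ·s + εᵢₜ,&nbsp;&nbsp;
(b₀ᵢ, b₁ᵢ) ~ N(0, G),

with s a centered/rescaled age and covariates x (sex, site, handedness,
ethnicity, ICV).  The subject deviation at a reference age a\* (60 y) is
the BLUP combination d_i(a\*) = b₀ᵢ + b₁ᵢ·s(a\*); adding it to the
population prediction gives the individualized total-GMV phenotype used
for genetic association.

**Patterns.** The subjects × ROIs deviation matrix is reduced by PCA
(15 components) and clustered by k-means (k = 2 by convention checks:
elbow + silhouette); pattern 1 is relabeled to the cluster with higher
baseline total GMV.

**Mirroring.** Annual percentage volume change APC = 100·(V_last −
V_first)/(V_first·Δt) per subject with ≥ 2 scans is smoothed over age
(cross-validated smoothing spline), evaluated at 15 y (development) and
55/75 y (aging), z-scored across cortical ROIs, and combined as
m_r = z_dev(r) − z_age(r); high m_r marks late-developing,
fast-declining ("last in, first out") regions.

**Transcriptomics.** PLS1 of regions × genes expression against a
cortical map (weights ∝ Xᵀy), explained variance as R² of the map on the
first score, inference by rotation-based spatial permutation of
spherical parcel centroids (add-one two-sided p), bootstrap gene Z
statistics with BH-FDR selection of signed gene sets.

**Genetics.** Variant QC (call rate, MAF, INFO), greedy LD clumping
(r² ≥ 0.1 within 250 kb), PRS averaged over 100 p-value thresholds
(0.005–0.5), and a covariate-adjusted per-SNP OLS scan with λ_GC and
clumped genome-wide significant hits (p < 5×10⁻⁸).

All inputs can be synthesized by `neuroaging.synth` with planted truth:
two-pattern cohorts, spherical parcellations, spatially smooth expression
with coupled genes, and LD-block genotypes with causal effects.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from neuroaging import synth, trajectory, patterns, mirroring

# adult cohort with two planted aging patterns (pi = 0.5)
cfg = synth.adult_config(n_subjects=600, pattern_mixing=0.5, seed=7)
cohort, truth = synth.generate_longitudinal_cohort(cfg)

dev, models = trajectory.fit_deviation_matrix(cohort, reference_age=60.0)
clus = patterns.PatternClusterer(n_components=15, k=2, seed=0).fit(dev, cohort=cohort)
print(f"pattern 1 share: {(clus.labels_ == 1).mean():.3f}")
print(f"ARI vs planted patterns: "
      f"{adjusted_rand_score(truth.labels.reindex(clus.labels_.index), clus.labels_):.3f}")
print(f"variance explained by 15 PCs: {clus.pca_.explained_variance_ratio.sum():.3f}")

# development/aging cohort pair with planted 'last in, first out' regions
dev_c, age_c, mtruth = synth.generate_mirrored_cohorts(n_dev=350, n_age=250, seed=7)
res = mirroring.mirroring_pipeline(dev_c, age_c)
print(f"spearman(z_dev, z_age): {res.spearman:.3f}")
print("top-3 mirroring ROIs:", list(res.scores.sort_values(ascending=False).head(3).index))
print("planted LIFO ROIs:   ", sorted(mtruth['lifo_rois']))
```

Output:

```
pattern 1 share: 0.535
ARI vs planted patterns: 0.941
variance explained by 15 PCs: 0.725
spearman(z_dev, z_age): -0.752
top-3 mirroring ROIs: ['insula', 'precuneus', 'fusiform']
planted LIFO ROIs:    ['fusiform', 'insula', 'precuneus']
```

The clustering recovers the planted mixture almost perfectly (ARI 0.94)
with a near-even pattern split, 15 PCs carry ~72% of deviation variance,
and the mirroring map ranks exactly the three planted late-in/first-out
regions on top with the expected negative development–aging coupling.

A `typer` CLI mirrors the library:
`neuroaging simulate|qc|fit-trajectories|cluster|curves|mirroring|pls|prs|scan --help`.

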