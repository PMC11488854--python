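"""Imaging-transcriptomics association via first-component PLS with
spatial permutation (spin) inference and bootstrap gene statistics.

The first PLS component of a regions x genes expression matrix X against a
cortical map y maximizes cov(Xw, y); with a single response its weight
vector is proportional to X^T y (equivalently the leading right singular
direction of the cross-covariance).  Explained variance is the R^2 of y on
the first score.  Significance of map-score associations respects spatial
autocorrelation through a rotation-based null: random 3D rotations are
applied to the spherical parcel centroids of the left hemisphere (and
their x-mirrored twin to the right), each rotated parcel is reassigned to
the nearest original centroid within hemisphere, and the statistic is
recomputed under each reassignment (two-sided add-one p).  Per-gene
uncertainty comes from bootstrap resampling of regions with sign-aligned
refits; genes are selected by signed direction at a fixed FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .exceptions import DegenerateInputError
from .maps import ZMap
from .synth.parcellation import Parcellation
from .contrasts import adjust_pvalues

__all__ = [
    "PLSMapRegressor",
    "SpinNull",
    "GeneStatTable",
    "fit_pls1",
    "generate_spin_permutations",
    "spin_pvalue",
    "bootstrap_gene_weights",
    "select_signed_genes",
]


def _as_series(y) -> pd.Series:
    if isinstance(y, ZMap):
        return y.values
    return pd.Series(y)


class PLSMapRegressor(BaseEstimator):
    """First-component PLS of gene expression against a cortical map.

    Gene columns are z-scored across regions before fitting (removes
    expression-scale dominance); the component sign is fixed so the
    Spearman correlation between scores and the map is non-negative.

    Attributes (after ``fit``): ``weights_`` (unit-norm gene weights),
    ``scores_`` (region scores t = Xw), ``explained_variance_`` (R^2 of
    the map on t), ``spearman_``.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y) -> "PLSMapRegressor":
        Xf = pd.DataFrame(X)
        ys = _as_series(y).reindex(Xf.index)
        if ys.isna().any():
            raise ValueError("map does not cover every expression region")
        yv = ys.to_numpy(dtype=float)
        if np.ptp(yv) == 0:
            raise DegenerateInputError("constant map")
        if len(Xf) < 10:
            raise ValueError("need at least 10 regions")
        M = Xf.to_numpy(dtype=float)
        mu = M.mean(axis=0)
        if self.standardize:
            sd = M.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
        else:
            sd = np.ones(M.shape[1])
        Z = (M - mu) / sd
        yc = yv - yv.mean()
        w = Z.T @ yc
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise DegenerateInputError("expression matrix is orthogonal to the map")
        w = w / nrm
        t = Z @ w
        rho = stats.spearmanr(t, yv).statistic
        if rho < 0:
            w, t, rho = -w, -t, -rho
        r = np.corrcoef(t, yv)[0, 1]
        self.weights_ = pd.Series(w, index=Xf.columns, name="w")
        self.scores_ = pd.Series(t, index=Xf.index, name="t")
        self.explained_variance_ = float(r**2)
        self.spearman_ = float(rho)
        self._mu, self._sd = mu, sd
        return self

    def transform(self, X) -> pd.Series:
        Z = (pd.DataFrame(X)[self.weights_.index].to_numpy(dtype=float) - self._mu) / self._sd
        return pd.Series(Z @ self.weights_.to_numpy(), index=pd.DataFrame(X).index)


def fit_pls1(X, y, standardize: bool = True) -> PLSMapRegressor:
    """Fit the first PLS component of expression against a cortical map."""
    return PLSMapRegressor(standardize=standardize).fit(X, y)


@dataclass
class SpinNull:
    """Rotation-based permutation indices over cortical ROIs.

    ``indices[k, i]`` is the source region whose value region ``i`` takes
    under permutation k.  Nearest-centroid reassignment may repeat a
    source region (values are carried, not permuted bijectively), the
    standard behavior of rotation-based nulls on parcellated maps.
    """

    indices: np.ndarray
    rois: list[str]
    seed: int | None = None
    rotations: np.ndarray | None = None  # (n_perm, 3, 3) left-hemisphere rotations

    @property
    def n_perm(self) -> int:
        return len(self.indices)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values)[self.indices]


def generate_spin_permutations(
    parcellation: Parcellation,
    n_perm: int = 10000,
    seed: int = 0,
    rotations: np.ndarray | None = None,
) -> SpinNull:
    """Spin null: one uniform random rotation per permutation, applied to
    the left-hemisphere centroids and x-mirrored for the right.

    ``rotations`` injects explicit (n_perm, 3, 3) rotation matrices in
    place of random draws (used for validation)."""
    left = parcellation.cortical("L")
    right = parcellation.cortical("R")
    if left[["x", "y", "z"]].isna().any().any() or right[["x", "y", "z"]].isna().any().any():
        raise ValueError("cortical parcels must all carry centroids")
    cl = left[["x", "y", "z"]].to_numpy(dtype=float)
    cr = right[["x", "y", "z"]].to_numpy(dtype=float)
    rois = left["roi"].tolist() + right["roi"].tolist()
    n_l = len(cl)

    if rotations is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        rots = Rotation.random(n_perm, rng=rng).as_matrix()
    else:
        rots = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
        n_perm = len(rots)
    mirror = np.diag([-1.0, 1.0, 1.0])
    rots_r = mirror @ rots @ mirror

    # rotated_l[k] = cl @ R_k^T ; assignment by maximal cosine similarity
    rot_l = np.einsum("kij,nj->kni", rots, cl)
    rot_r = np.einsum("kij,nj->kni", rots_r, cr)
    idx_l = np.argmax(np.einsum("kni,mi->knm", rot_l, cl), axis=2)
    idx_r = np.argmax(np.einsum("kni,mi->knm", rot_r, cr), axis=2)
    indices = np.concatenate([idx_l, idx_r + n_l], axis=1)
    return SpinNull(indices=indices, rois=rois, seed=seed, rotations=rots)


def spin_pvalue(observed_stat: float, stat_under_permutation, y, spin: SpinNull) -> float:
    """Two-sided add-one permutation p-value.

    ``stat_under_permutation(y_perm)`` recomputes the statistic for a
    permuted map; ``y`` must be ordered like ``spin.rois``.
    """
    yv = _as_series(y).reindex(spin.rois).to_numpy(dtype=float)
    if np.isnan(yv).any():
        raise ValueError("map does not cover the spin-null ROI set")
    if np.ptp(yv) == 0:
        raise DegenerateInputError("constant map")
    null = np.array([stat_under_permutation(yv[p]) for p in spin.indices], dtype=float)
    if not np.isfinite(null).all():
        raise ValueError("statistic is not finite under all permutations")
    exceed = int(np.sum(np.abs(null) >= abs(observed_stat)))
    return (1.0 + exceed) / (spin.n_perm + 1.0)


@dataclass
class GeneStatTable:
    table: pd.DataFrame  # columns: w, se, z, p, q, sign
    n_boot: int
    n_redrawn: int = 0


def bootstrap_gene_weights(
    X, y, n_boot: int = 1000, seed: int = 0, standardize: bool = True
) -> GeneStatTable:
    """Bootstrap (regions resampled with replacement) SEs for PLS1 weights.

    Each refit component's sign is aligned to the original by the
    correlation of its scores with the original scores on the resampled
    regions; degenerate resamples (constant map) are redrawn and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    Xf = pd.DataFrame(X)
    ys = _as_series(y).reindex(Xf.index)
    base = fit_pls1(Xf, ys, standardize=standardize)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(Xf)
    boots = np.empty((n_boot, Xf.shape[1]))
    t_orig = base.scores_.to_numpy()
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = ys.iloc[idx]
        if np.ptp(yb.to_numpy(dtype=float)) == 0:
            n_redrawn += 1
            continue
        Xb = Xf.iloc[idx]
        Xb = Xb.set_axis(range(n), axis=0)
        fb = fit_pls1(Xb, yb.set_axis(range(n)), standardize=standardize)
        wb = fb.weights_.to_numpy()
        tb = fb.scores_.to_numpy()
        align = np.corrcoef(tb, t_orig[idx])[0, 1]
        if align < 0:
            wb = -wb
        boots[b] = wb
        b += 1
    se = boots.std(axis=0, ddof=1)
    se[se == 0] = np.nan
    w = base.weights_.to_numpy()
    zscores = w / se
    p = 2.0 * stats.norm.sf(np.abs(zscores))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = adjust_pvalues(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "w": w,
            "se": se,
            "z": zscores,
            "p": p,
            "q": q,
            "sign": np.sign(w).astype(int),
        },
        index=base.weights_.index,
    )
    return GeneStatTable(table=table, n_boot=n_boot, n_redrawn=n_redrawn)


def select_signed_genes(
    dev_stats: GeneStatTable, age_stats: GeneStatTable, fdr: float = 0.005
) -> dict[str, list[str]]:
    """Genes positively tied to development (set A) and negatively to aging
    (set B) at the given FDR."""
    dev, age = dev_stats.table, age_stats.table
    shared = dev.index.intersection(age.index)
    a = dev.loc[shared]
    b = age.loc[shared]
    set_a = sorted(a.index[(a["q"] <= fdr) & (a["sign"] > 0)])
    set_b = sorted(b.index[(b["q"] <= fdr) & (b["sign"] < 0)])
    return {
        "delayed_development": set_a,
        "accelerated_aging": set_b,
        "n_delayed_development": len(set_a),
        "n_accelerated_aging": len(set_b),
    }
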