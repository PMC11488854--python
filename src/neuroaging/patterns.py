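"""Population clustering of brain-aging trajectories.

The subjects x ROIs deviation matrix is reduced by PCA (centered,
unscaled: all columns share mm^3 units) and subjects are clustered by
k-means in PC space (k-means++ with multiple restarts, fixed seed).
The number of clusters is guided by the elbow (within-cluster sum of
squares) and the mean silhouette ("contour coefficient").  With k = 2
the labels follow the convention that pattern 1 is the cluster with the
higher mean baseline total gray-matter volume (the slower-declining
pattern), so labels are comparable across runs and cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .cohort import Cohort
from .exceptions import DegenerateInputError
from .trajectory import DeviationMatrix

__all__ = [
    "PCAResult",
    "PatternAssignment",
    "PatternClusterer",
    "reduce_deviations_pca",
    "choose_k",
    "cluster_patterns",
    "apply_labeling_convention",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # ROIs x k, orthonormal columns
    scores: pd.DataFrame            # subjects x k
    explained_variance_ratio: np.ndarray
    mean: pd.Series | None = None   # training column means (for projection)


@dataclass
class PatternAssignment:
    labels: pd.Series               # subject -> {1..k}
    centroids: np.ndarray           # k x n_components, PC space
    inertia: float
    seed: int | None = None
    n_restarts: int = 20
    silhouette_per_k: dict[int, float] = field(default_factory=dict)
    wss_per_k: dict[int, float] = field(default_factory=dict)
    tie_break: str | None = None

    def to_tsv(self, path) -> None:
        self.labels.rename("pattern").rename_axis("subject_id").to_csv(path, sep="\t")


def _deviation_frame(deviations) -> pd.DataFrame:
    if isinstance(deviations, DeviationMatrix):
        return deviations.data
    return pd.DataFrame(deviations)


def reduce_deviations_pca(deviations, n_components: int = 15) -> PCAResult:
    """PCA of the centered (unscaled) deviation matrix."""
    mat = _deviation_frame(deviations).dropna(axis=0)
    n_components = int(n_components)
    max_rank = min(mat.shape[0] - 1, mat.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components truncated from {n_components} to matrix rank {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank
    if np.allclose(mat.var(axis=0, ddof=0), 0.0):
        raise DegenerateInputError("deviation matrix has zero variance (identical rows)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(mat.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=mat.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=mat.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pd.Series(pca.mean_, index=mat.columns),
    )


def choose_k(scores, k_range=range(2, 9), seed: int = 0, n_restarts: int = 20) -> dict:
    """Elbow (WSS) and mean-silhouette diagnostics over candidate k."""
    X = _scores_array(scores)
    ks = [k for k in k_range if k >= 2]
    if not ks:
        raise ValueError("k_range must contain values >= 2")
    ks = [k for k in ks if k < len(X)] or [2]
    wss, sil = {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, km.labels_))
    recommended = max(sil, key=sil.get)
    return {"wss": wss, "silhouette": sil, "recommended_k": recommended}


def _scores_array(scores) -> np.ndarray:
    if isinstance(scores, PCAResult):
        return scores.scores.to_numpy(dtype=float)
    return np.asarray(pd.DataFrame(scores), dtype=float)


def _scores_index(scores) -> pd.Index:
    if isinstance(scores, PCAResult):
        return scores.scores.index
    s = pd.DataFrame(scores)
    return s.index


def cluster_patterns(
    scores, k: int = 2, seed: int = 0, n_restarts: int = 20
) -> PatternAssignment:
    """Best-of-restarts k-means in PC space; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _scores_array(scores)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    sizes = np.bincount(km.labels_, minlength=k)
    if (sizes == 0).any():
        raise DegenerateInputError("k-means converged with an empty cluster")
    labels = pd.Series(km.labels_ + 1, index=_scores_index(scores), name="pattern")
    return PatternAssignment(
        labels=labels,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def apply_labeling_convention(
    assignment: PatternAssignment, cohort: Cohort
) -> PatternAssignment:
    """Permute 2-cluster labels so pattern 1 has higher mean baseline TGMV.

    Idempotent; a tie in means is broken deterministically by cluster size
    (the larger cluster becomes pattern 1) and recorded.
    """
    labels = assignment.labels
    if labels.nunique() != 2:
        raise ValueError("labeling convention applies to k = 2 only")
    base = cohort.baseline().set_index("subject_id")["tgmv"]
    means = base.groupby(labels.reindex(base.index)).mean()
    tie_break = None
    if np.isclose(means.loc[1], means.loc[2]):
        sizes = labels.value_counts()
        higher = int(sizes.idxmax())
        tie_break = "cluster size"
    else:
        higher = int(means.idxmax())
    if higher == 1:
        new_labels = labels.copy()
        centroids = assignment.centroids
    else:
        new_labels = labels.map({1: 2, 2: 1})
        centroids = assignment.centroids[::-1].copy()
    return PatternAssignment(
        labels=new_labels.rename("pattern"),
        centroids=centroids,
        inertia=assignment.inertia,
        seed=assignment.seed,
        n_restarts=assignment.n_restarts,
        silhouette_per_k=assignment.silhouette_per_k,
        wss_per_k=assignment.wss_per_k,
        tie_break=tie_break,
    )


class PatternClusterer(BaseEstimator, ClusterMixin):
    """PCA + k-means pipeline over a deviation matrix.

    ``fit`` expects the subjects x ROIs deviation matrix; pass the cohort
    to ``fit`` (keyword ``cohort``) to apply the baseline-TGMV labeling
    convention for k = 2.  ``labels_`` holds patterns in {1..k}.
    """

    def __init__(
        self,
        n_components: int = 15,
        k: int = 2,
        seed: int = 0,
        n_restarts: int = 20,
        k_diagnostics: tuple[int, int] | None = (2, 8),
    ):
        self.n_components = n_components
        self.k = k
        self.seed = seed
        self.n_restarts = n_restarts
        self.k_diagnostics = k_diagnostics

    def fit(self, X, y=None, cohort: Cohort | None = None) -> "PatternClusterer":
        self.pca_ = reduce_deviations_pca(X, self.n_components)
        if self.k_diagnostics is not None:
            lo, hi = self.k_diagnostics
            self.diagnostics_ = choose_k(
                self.pca_, range(lo, hi + 1), seed=self.seed, n_restarts=self.n_restarts
            )
        assignment = cluster_patterns(
            self.pca_, k=self.k, seed=self.seed, n_restarts=self.n_restarts
        )
        if self.k == 2 and cohort is not None:
            assignment = apply_labeling_convention(assignment, cohort)
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        return self

    def fit_predict(self, X, y=None, **fit_kwargs) -> pd.Series:
        return self.fit(X, **fit_kwargs).labels_

    def predict(self, X) -> pd.Series:
        """Assign new deviation rows to the fitted patterns."""
        mat = _deviation_frame(X)[self.pca_.loadings.index]
        centered = mat.to_numpy(dtype=float) - self.pca_.mean.to_numpy()
        scores = centered @ self.pca_.loadings.to_numpy()
        d = ((scores[:, None, :] - self.assignment_.centroids[None]) ** 2).sum(-1)
        return pd.Series(d.argmin(1) + 1, index=mat.index, name="pattern")
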