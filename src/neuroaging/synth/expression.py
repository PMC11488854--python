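"""Synthetic regional gene-expression matrix.

Each gene is a draw from a Gaussian process on the sphere of cortical
centroids with a squared-exponential kernel in great-circle distance, so
expression fields carry realistic spatial autocorrelation.  A chosen subset
of genes is coupled (with stated correlation) to a target cortical map,
giving the imaging-transcriptomics stage a recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import ConfigurationError
from ..maps import RegionMap
from .parcellation import Parcellation

__all__ = ["ExpressionTruth", "generate_expression"]


@dataclass
class ExpressionTruth:
    coupled_genes: list[str]
    coupling_r: float


def _great_circle_matrix(points: np.ndarray) -> np.ndarray:
    dots = np.clip(points @ points.T, -1.0, 1.0)
    return np.arccos(dots)


def generate_expression(
    parcellation: Parcellation,
    n_genes: int = 500,
    smoothness: float = 0.6,
    coupled_map: RegionMap | pd.Series | None = None,
    n_coupled: int = 0,
    coupling_r: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Draw a regions x genes expression matrix.

    Parameters
    ----------
    smoothness : kernel length-scale in radians of great-circle distance;
        values near 0 give i.i.d. (white) expression across regions.
    coupled_map : cortical map the first ``n_coupled`` randomly chosen genes
        correlate with (correlation ``coupling_r``).
    """
    if n_coupled > n_genes:
        raise ConfigurationError("n_coupled cannot exceed n_genes")
    if not 0 <= abs(coupling_r) <= 1:
        raise ConfigurationError("|coupling_r| must be <= 1")
    cortical = parcellation.cortical()
    rois = cortical["roi"].tolist()
    pts = cortical[["x", "y", "z"]].to_numpy(dtype=float)
    n_regions = len(rois)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if smoothness > 0:
        d = _great_circle_matrix(pts)
        k = np.exp(-0.5 * (d / smoothness) ** 2)
        k[np.diag_indices_from(k)] += 1e-8
        chol = np.linalg.cholesky(k)
    else:
        chol = np.eye(n_regions)

    expr = chol @ rng.standard_normal((n_regions, n_genes))

    coupled_genes: list[str] = []
    gene_ids = [f"GENE{j:05d}" for j in range(n_genes)]
    if n_coupled > 0:
        if coupled_map is None:
            raise ConfigurationError("n_coupled > 0 requires a coupled_map")
        target = (
            coupled_map.values if isinstance(coupled_map, RegionMap) else coupled_map
        )
        target = pd.Series(target).reindex(rois)
        if target.isna().any():
            raise ConfigurationError(
                "coupled_map must cover every cortical ROI of the parcellation"
            )
        y = target.to_numpy(dtype=float)
        y = (y - y.mean()) / y.std(ddof=1)
        idx = rng.choice(n_genes, size=n_coupled, replace=False)
        for j in idx:
            g = expr[:, j]
            g = (g - g.mean()) / g.std(ddof=1)
            mixed = coupling_r * y + np.sqrt(1 - coupling_r**2) * (
                g - y * (g @ y) / (y @ y)
            ) / max(np.linalg.norm(g - y * (g @ y) / (y @ y)) / np.sqrt(n_regions - 1), 1e-12)
            expr[:, j] = y if abs(coupling_r) == 1.0 else mixed
        coupled_genes = [gene_ids[j] for j in sorted(idx)]

    matrix = pd.DataFrame(expr, index=pd.Index(rois, name="roi"), columns=gene_ids)
    return matrix, ExpressionTruth(coupled_genes=coupled_genes, coupling_r=coupling_r)
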