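"""Synthetic cortical parcellation with spherical centroids.

Cortical parcel centroids are placed on the unit sphere with a Fibonacci
lattice (well separated by construction) for the left hemisphere and
x-mirrored for the right, standing in for registered Desikan-Killiany
spheres.  Subcortical structures carry no centroid and never enter the
spatial (spin) permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..cohort import CORTICAL_ROIS, SUBCORTICAL_ROIS
from ..exceptions import ConfigurationError

__all__ = ["Parcellation", "generate_parcellation"]


@dataclass
class Parcellation:
    """Table with columns roi, hemisphere, x, y, z, cortical."""

    table: pd.DataFrame

    def cortical(self, hemisphere: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["cortical"]]
        if hemisphere is not None:
            t = t[t["hemisphere"] == hemisphere]
        return t

    def centroids(self, hemisphere: str) -> np.ndarray:
        t = self.cortical(hemisphere)
        return t[["x", "y", "z"]].to_numpy(dtype=float)

    def cortical_rois(self) -> list[str]:
        return self.table.loc[self.table["cortical"], "roi"].tolist()

    @property
    def n_cortical(self) -> int:
        return int(self.table["cortical"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        t = pd.read_csv(path, sep="\t")
        t["cortical"] = t["cortical"].astype(bool)
        return cls(t)


def _fibonacci_sphere(n: int, jitter_rng: np.random.Generator | None) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = (1 + np.sqrt(5.0)) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    if jitter_rng is not None:
        # small deterministic jitter so no two runs of different n share points
        theta = theta + jitter_rng.uniform(0, 2 * np.pi)
    r = np.sqrt(np.clip(1 - z**2, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def generate_parcellation(
    n_cortical_per_hemisphere: int = 33,
    seed: int = 0,
    include_subcortical: bool = True,
) -> Parcellation:
    """Build a synthetic parcellation with L/R mirror-pair centroids.

    Left-hemisphere centroids come from a Fibonacci lattice (rotated by a
    seed-derived phase); the right hemisphere is its mirror through the
    x = 0 plane, mimicking interhemispheric symmetry.
    """
    n = n_cortical_per_hemisphere
    if n < 4:
        raise ConfigurationError("need at least 4 cortical parcels per hemisphere")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    left = _fibonacci_sphere(n, rng)
    right = left * np.array([-1.0, 1.0, 1.0])

    if n == len(CORTICAL_ROIS):
        names = list(CORTICAL_ROIS)
    else:
        names = [f"parcel{i:03d}" for i in range(n)]

    rows = []
    for hemi, pts in (("L", left), ("R", right)):
        for name, p in zip(names, pts):
            rows.append((f"{hemi}_{name}", hemi, p[0], p[1], p[2], True))
    if include_subcortical:
        for name in SUBCORTICAL_ROIS:
            rows.append((name, "B", np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["roi", "hemisphere", "x", "y", "z", "cortical"]
    )
    return Parcellation(table)
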