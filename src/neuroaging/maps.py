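"""Parcellated scalar maps: one value per cortical ROI.

A :class:`RegionMap` holds a quantity evaluated per region (for example the
annual percentage volume change at a target age); a :class:`ZMap` is its
standardization across cortical regions (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError

__all__ = ["RegionMap", "ZMap"]


@dataclass
class RegionMap:
    values: pd.Series  # roi -> value
    target_age: float | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values)
        if self.values.index.duplicated().any():
            raise DegenerateInputError("region map has duplicated ROI entries")

    @property
    def rois(self) -> pd.Index:
        return self.values.index

    def standardize(self) -> "ZMap":
        x = self.values.astype(float)
        if len(x) < 3:
            raise DegenerateInputError("need at least 3 regions to standardize")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateInputError("region map has zero variance")
        return ZMap(values=(x - x.mean()) / sd, parent=self)

    def to_frame(self) -> pd.DataFrame:
        return self.values.rename("value").rename_axis("roi").reset_index()


@dataclass
class ZMap:
    values: pd.Series
    parent: RegionMap | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values)

    @property
    def rois(self) -> pd.Index:
        return self.values.index
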