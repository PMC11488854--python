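"""Long-format longitudinal cohort container.

A cohort is one row per (subject, visit) with demographic covariates,
intracranial volume, per-ROI gray-matter volumes and total gray-matter
volume (TGMV).  All downstream model fits consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import IntegrityError, SchemaError

#: Bilaterally averaged cortical parcels (Desikan-Killiany style, 33 parcels)
CORTICAL_ROIS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "transversetemporal",
)

#: Subcortical structures (ASEG style, 7 structures)
SUBCORTICAL_ROIS: tuple[str, ...] = (
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens",
)

DEFAULT_ROIS: tuple[str, ...] = CORTICAL_ROIS + SUBCORTICAL_ROIS

#: Columns every visit table must carry besides the ROI volumes
MANDATORY_COLUMNS = (
    "subject_id", "visit", "age", "sex", "site",
    "handedness", "ethnicity", "icv", "tgmv",
)


@dataclass
class Cohort:
    """One row per visit; ``roi_columns`` name the per-ROI volume columns."""

    data: pd.DataFrame
    roi_columns: tuple[str, ...] = field(default=DEFAULT_ROIS)

    def __post_init__(self) -> None:
        self.roi_columns = tuple(self.roi_columns)
        missing = [c for c in MANDATORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"visit table is missing columns: {missing}")
        missing_roi = [c for c in self.roi_columns if c not in self.data.columns]
        if missing_roi:
            raise SchemaError(f"visit table is missing ROI columns: {missing_roi}")
        dup = self.data.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            pairs = self.data.loc[dup, ["subject_id", "visit"]].to_records(index=False)
            raise IntegrityError(f"duplicate (subject, visit) pairs: {list(pairs)[:5]}")

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.data)

    def subjects(self) -> pd.Index:
        return pd.Index(self.data["subject_id"].unique(), name="subject_id")

    def baseline(self) -> pd.DataFrame:
        """First visit per subject (lowest age)."""
        d = self.data.sort_values(["subject_id", "age"], kind="mergesort")
        return d.groupby("subject_id", sort=False).head(1)

    def select_subjects(self, keep) -> "Cohort":
        mask = self.data["subject_id"].isin(set(keep))
        return Cohort(self.data.loc[mask].reset_index(drop=True), self.roi_columns)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.roi_columns != other.roi_columns:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.data.reset_index(drop=True),
                other.data.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True
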