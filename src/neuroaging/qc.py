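"""Visit-table ingestion and sample/volume quality control.

Implements the two sample-screening rules used with population imaging
cohorts: removal of subjects whose total gray-matter volume, intracranial
volume or any regional volume lies beyond a fixed number of standard
deviations from the sample mean (default 4, computed on the pre-exclusion
baseline sample), and removal of subjects carrying diagnosis codes from a
configurable exclusion list (the ICD-10 screening mechanism).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DEFAULT_ROIS, MANDATORY_COLUMNS, Cohort
from .exceptions import SchemaError

__all__ = ["QCReport", "load_visit_table", "apply_volume_qc", "exclude_by_code_list"]


@dataclass
class QCReport:
    """Pure metadata: per-rule exclusion counts and the excluded subjects."""

    n_input: int
    n_excluded_by_rule: dict[str, int] = field(default_factory=dict)
    excluded_ids: dict[str, list] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        all_ids = set()
        for ids in self.excluded_ids.values():
            all_ids.update(ids)
        return len(all_ids)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "n_excluded": self.n_excluded,
                "n_retained": self.n_retained,
                "n_excluded_by_rule": self.n_excluded_by_rule,
                "excluded_ids": {k: sorted(map(str, v)) for k, v in self.excluded_ids.items()},
                "warnings": self.warnings,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def load_visit_table(path, roi_columns=None, sep: str = "\t") -> Cohort:
    """Read a long-format visit table into a :class:`Cohort`.

    ROI columns default to every non-mandatory numeric column; pass
    ``roi_columns`` to pin the atlas explicitly.  Unparseable numeric
    entries are reported with their line numbers.
    """
    raw = pd.read_csv(path, sep=sep)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if roi_columns is None:
        if all(r in raw.columns for r in DEFAULT_ROIS):
            roi_columns = DEFAULT_ROIS
        else:
            roi_columns = tuple(
                c for c in raw.columns if c not in MANDATORY_COLUMNS
            )
    numeric_cols = ["age", "icv", "tgmv", *roi_columns]
    bad_lines: list[int] = []
    for col in numeric_cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        newly_bad = coerced.isna() & raw[col].notna()
        if newly_bad.any():
            # +2: header line plus 1-based indexing
            bad_lines.extend((raw.index[newly_bad] + 2).tolist())
        raw[col] = coerced
    if bad_lines:
        raise SchemaError(
            f"{path}: unparseable numeric values at lines {sorted(set(bad_lines))[:20]}"
        )
    return Cohort(raw, tuple(roi_columns))


def apply_volume_qc(
    cohort: Cohort, sd_threshold: float = 4.0
) -> tuple[Cohort, QCReport]:
    """Drop subjects with any screened volume beyond ``sd_threshold`` SDs.

    Screened quantities: TGMV, ICV and every regional volume, evaluated at
    each subject's baseline visit; means and SDs come from the full
    pre-exclusion baseline sample.
    """
    base = cohort.baseline().set_index("subject_id")
    if len(base) < 2:
        raise ValueError("volume QC needs at least 2 subjects")
    report = QCReport(n_input=len(base))
    screened = ["tgmv", "icv", *cohort.roi_columns]
    for col in screened:
        x = base[col].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            msg = f"rule '{col}' skipped: zero-variance column"
            report.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        out = x.index[np.abs(x - mu) > sd_threshold * sd]
        report.n_excluded_by_rule[col] = len(out)
        if len(out):
            report.excluded_ids[col] = list(out)
    drop = set().union(*report.excluded_ids.values()) if report.excluded_ids else set()
    keep = [s for s in base.index if s not in drop]
    return cohort.select_subjects(keep), report


def exclude_by_code_list(
    cohort: Cohort,
    subject_code_table: pd.DataFrame,
    exclusion_codes,
) -> tuple[Cohort, QCReport]:
    """Remove subjects carrying any code in ``exclusion_codes``.

    ``subject_code_table`` needs columns ``subject_id`` and ``code``
    (one row per diagnosis code).  Codes for subjects absent from the
    cohort are ignored with a warning.  Order-independent.
    """
    exclusion = set(exclusion_codes)
    subjects = set(cohort.subjects())
    report = QCReport(n_input=cohort.n_subjects)

    flagged = subject_code_table[subject_code_table["code"].isin(exclusion)]
    unknown = sorted(set(flagged["subject_id"]) - subjects)
    if unknown:
        msg = f"{len(unknown)} flagged subjects not present in cohort; ignored"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    to_drop = sorted(set(flagged["subject_id"]) & subjects)
    report.n_excluded_by_rule["exclusion_codes"] = len(to_drop)
    if to_drop:
        report.excluded_ids["exclusion_codes"] = to_drop
    keep = [s for s in cohort.subjects() if s not in set(to_drop)]
    return cohort.select_subjects(keep), report
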