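"""Development-aging "last in, first out" mirroring maps.

For every subject with at least two scans, the annual percentage volume
change (APC) of each ROI is

    APC = 100 * (V_follow - V_base) / (V_base * dt)   [%/year],

using the first and last scans.  Per-ROI APC is regressed on age (the
midpoint age of the scan pair) with a cross-validated smoothing spline,
evaluated at target ages (15 y for the developmental cohort; 55 y early /
75 y late aging for the adult cohort), and standardized across cortical
ROIs.  The mirroring score of a region is

    m_r = z_dev(r) - z_age(r):

large m_r marks regions relatively preserved during development but
relatively fast-declining in aging - the "last in, first out" signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .curves import SmoothingSplineRegressor
from .exceptions import DegenerateInputError
from .maps import RegionMap, ZMap

__all__ = [
    "APCRecord",
    "MirroringMap",
    "compute_subject_apc",
    "smooth_apc_vs_age",
    "evaluate_apc_map",
    "standardize_map",
    "mirroring_scores",
    "mirroring_pipeline",
]


@dataclass
class APCRecord:
    subject: str
    roi: str
    apc: float          # %/year
    midpoint_age: float
    baseline_volume: float
    dt: float


@dataclass
class MirroringMap:
    scores: pd.Series                 # roi -> m_r
    z_dev: ZMap
    z_age: ZMap
    spearman: float
    spearman_p: float


def _first_last(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    d = cohort.data.sort_values(["subject_id", "age"], kind="mergesort")
    first = d.groupby("subject_id", sort=False).head(1).set_index("subject_id")
    last = d.groupby("subject_id", sort=False).tail(1).set_index("subject_id")
    multi = first.index[(last["age"] - first["age"]) > 0]
    return first.loc[multi], last.loc[multi]


def _apc_from_pairs(first: pd.DataFrame, last: pd.DataFrame, roi: str) -> pd.DataFrame:
    v0 = first[roi].astype(float)
    v1 = last[roi].astype(float)
    dt = last["age"] - first["age"]
    ok = (v0 > 0) & np.isfinite(v0) & np.isfinite(v1)
    out = pd.DataFrame(
        {
            "subject": first.index[ok],
            "roi": roi,
            "apc": (100.0 * (v1 - v0) / (v0 * dt))[ok].to_numpy(),
            "midpoint_age": (0.5 * (first["age"] + last["age"]))[ok].to_numpy(),
            "baseline_volume": v0[ok].to_numpy(),
            "dt": dt[ok].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def compute_subject_apc(cohort: Cohort, roi: str) -> pd.DataFrame:
    """APC records for one ROI; subjects with a single scan are excluded.

    Multi-visit subjects contribute one record from their first/last scan
    pair, keeping records independent across subjects.  Records with a
    non-positive or missing baseline volume are skipped.
    """
    first, last = _first_last(cohort)
    if (last["age"] - first["age"] <= 0).any():
        raise ValueError("zero time between scans")
    return _apc_from_pairs(first, last, roi)


def smooth_apc_vs_age(
    records: pd.DataFrame,
    cv_folds: int = 5,
    lam_grid=None,
    seed: int = 0,
    min_records: int = 30,
    min_span: float = 5.0,
    method: str = "cv",
    bin_width: float = 0.25,
) -> SmoothingSplineRegressor:
    """Cubic smoothing spline of APC on age with a cross-validated penalty.

    ``method="cv"`` (default) grid-searches ``lam_grid`` by
    ``cv_folds``-fold prediction error; ``method="gcv"`` uses generalized
    cross-validation instead.  Midpoint ages are binned to ``bin_width``
    years (weighted) before the solve.
    """
    if len(records) < min_records:
        raise ValueError(f"need >= {min_records} APC records, got {len(records)}")
    ages = records["midpoint_age"].to_numpy(dtype=float)
    if np.ptp(ages) < min_span:
        raise DegenerateInputError(
            f"age span {np.ptp(ages):.2f} y is below the required {min_span} y"
        )
    lam = "cv" if method == "cv" else "gcv"
    return SmoothingSplineRegressor(
        lam=lam, lam_grid=lam_grid, cv=cv_folds, seed=seed, bin_width=bin_width
    ).fit(ages, records["apc"].to_numpy(dtype=float))


def evaluate_apc_map(
    curves: Mapping[str, SmoothingSplineRegressor],
    target_age: float,
    cohort_tag: str | None = None,
    max_missing_fraction: float = 0.2,
    extrapolation_tolerance: float = 1.0,
) -> RegionMap:
    """Evaluate each ROI's APC curve at ``target_age``.

    A target within ``extrapolation_tolerance`` years of a curve's fitted
    age support is evaluated by the spline's boundary extension (scan-wave
    designs routinely leave target ages just outside the observed midpoint
    range); further out the ROI is flagged missing.
    """
    values, missing = {}, []
    for roi, curve in curves.items():
        if curve is None:
            missing.append(roi)
            continue
        lo, hi = curve.support_
        if not lo - extrapolation_tolerance <= target_age <= hi + extrapolation_tolerance:
            missing.append(roi)
            continue
        values[roi] = float(curve.predict(target_age))
    if len(missing) > max_missing_fraction * len(curves):
        raise ValueError(
            f"{len(missing)}/{len(curves)} ROIs missing at age {target_age}: {missing[:10]}"
        )
    return RegionMap(pd.Series(values), target_age=target_age, cohort=cohort_tag)


def standardize_map(region_map: RegionMap) -> ZMap:
    """z-score across cortical ROIs (sample SD, n-1)."""
    return region_map.standardize()


def mirroring_scores(z_dev: ZMap, z_age: ZMap) -> MirroringMap:
    """m_r = z_dev(r) - z_age(r), with the Spearman coupling of the maps.

    Antisymmetric by construction: swapping the two maps flips the sign.
    """
    dev, age = z_dev.values, z_age.values
    if set(dev.index) != set(age.index):
        diff = sorted(set(dev.index) ^ set(age.index))
        raise ValueError(f"ROI sets differ; symmetric difference: {diff[:10]}")
    age = age.reindex(dev.index)
    rho, p = stats.spearmanr(dev.to_numpy(), age.to_numpy())
    return MirroringMap(
        scores=(dev - age).rename("mirroring"),
        z_dev=z_dev,
        z_age=z_age,
        spearman=float(rho),
        spearman_p=float(p),
    )


def mirroring_pipeline(
    dev_cohort: Cohort,
    age_cohort: Cohort,
    rois=None,
    dev_age: float = 15.0,
    aging_age: float = 55.0,
    cv_folds: int = 5,
    lam_grid=None,
    seed: int = 0,
    method: str = "cv",
) -> MirroringMap:
    """End-to-end: APC records -> smoothed curves -> z-maps -> mirroring."""
    if rois is None:
        rois = [r for r in dev_cohort.roi_columns if r in age_cohort.roi_columns]
    fl_dev = _first_last(dev_cohort)
    fl_age = _first_last(age_cohort)
    curves_dev, curves_age = {}, {}
    for roi in rois:
        rec_dev = _apc_from_pairs(*fl_dev, roi)
        rec_age = _apc_from_pairs(*fl_age, roi)
        try:
            curves_dev[roi] = smooth_apc_vs_age(
                rec_dev, cv_folds=cv_folds, lam_grid=lam_grid, seed=seed, method=method
            )
            curves_age[roi] = smooth_apc_vs_age(
                rec_age, cv_folds=cv_folds, lam_grid=lam_grid, seed=seed, method=method
            )
        except (ValueError, DegenerateInputError):
            curves_dev[roi] = None
            curves_age[roi] = None
    map_dev = evaluate_apc_map(curves_dev, dev_age, cohort_tag="development")
    map_age = evaluate_apc_map(curves_age, aging_age, cohort_tag="aging")
    common = map_dev.values.index.intersection(map_age.values.index)
    z_dev = RegionMap(map_dev.values.loc[common], dev_age, "development").standardize()
    z_age = RegionMap(map_age.values.loc[common], aging_age, "aging").standardize()
    return mirroring_scores(z_dev, z_age)
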