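"""Smooth population volume-age curves and their rates of change.

The mean volume trajectory of each ROI (optionally per subject group) is a
penalized natural cubic smoothing spline of age fitted to covariate- and
subject-adjusted volumes, emulating additive-mixed-model age curves:
subject random effects estimated by the trajectory mixed model are removed
(individual deviations only - group means of the random effects are kept,
so between-group contrasts survive), and the smoothing penalty is selected
by generalized cross-validation or k-fold cross-validation.  Rates of
change are analytic derivatives of the fitted spline basis, never finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import Cohort
from .exceptions import DegenerateInputError
from .trajectory import ROITrajectoryLMM

__all__ = [
    "SmoothingSplineRegressor",
    "PopulationCurve",
    "fit_population_curve",
    "curve_rate_of_change",
]


class SmoothingSplineRegressor(BaseEstimator, RegressorMixin):
    """Natural cubic smoothing spline with data-driven penalty.

    Parameters
    ----------
    lam : a positive float fixes the penalty; ``"gcv"`` selects it by
        generalized cross-validation (scipy's criterion); ``"cv"`` selects
        it by k-fold cross-validation over ``lam_grid``.
    lam_grid : candidate penalties for ``lam="cv"`` (log-spaced default).
    cv : number of folds for ``lam="cv"``.
    seed : fold-assignment seed.

    Duplicate abscissae are pooled (weighted by multiplicity), the standard
    reduction for smoothing splines; ``bin_width`` optionally rounds the
    abscissa first (weighted binning), shrinking the solve when x is
    effectively continuous.  ``effective_df`` (trace of the hat matrix) is
    computed lazily because it costs one smoother application per distinct
    abscissa.
    """

    def __init__(
        self, lam="gcv", lam_grid=None, cv: int = 5, seed: int = 0, bin_width=None
    ):
        self.lam = lam
        self.lam_grid = lam_grid
        self.cv = cv
        self.seed = seed
        self.bin_width = bin_width

    # -- helpers ---------------------------------------------------------
    def _pool(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.bin_width:
            x = np.round(x / self.bin_width) * self.bin_width
        order = np.argsort(x, kind="mergesort")
        x, y = x[order], y[order]
        ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
        uy = np.bincount(inv, weights=y) / counts
        return ux, uy, counts.astype(float)

    @staticmethod
    def _fit_spline(x, y, w, lam) -> BSpline:
        return make_smoothing_spline(x, y, w=w, lam=lam)

    def _cv_lam(self, x, y, rng) -> float:
        grid = (
            np.asarray(self.lam_grid, dtype=float)
            if self.lam_grid is not None
            else np.logspace(-4, 5, 10)
        )
        n = len(x)
        folds = rng.permutation(n) % self.cv
        errs = np.zeros(len(grid))
        for f in range(self.cv):
            test = folds == f
            ux, uy, w = self._pool(x[~test], y[~test])
            if len(ux) < 5:
                continue
            xt = np.clip(x[test], ux[0], ux[-1])
            for g, lam in enumerate(grid):
                spl = self._fit_spline(ux, uy, w, lam)
                errs[g] += float(np.sum((spl(xt) - y[test]) ** 2))
        return float(grid[int(np.argmin(errs))])

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None) -> "SmoothingSplineRegressor":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        ux, uy, w = self._pool(x, y)
        if len(ux) < 5:
            raise DegenerateInputError(
                "smoothing spline needs >= 5 distinct abscissa values"
            )
        if np.ptp(ux) <= 0:
            raise DegenerateInputError("degenerate age spread")
        if self.lam == "cv":
            rng = np.random.default_rng(np.random.SeedSequence(self.seed))
            self.lam_ = self._cv_lam(x, y, rng)
        elif self.lam == "gcv":
            self.lam_ = None
        else:
            self.lam_ = float(self.lam)
        self.spline_ = self._fit_spline(ux, uy, w, self.lam_)
        if self.lam_ is None:
            self.lam_ = "gcv"
        self._ux, self._uy, self._w = ux, uy, w
        self.support_ = (float(ux[0]), float(ux[-1]))
        resid = y - self.spline_(x)
        self.n_obs_ = len(x)
        self._rss = float(np.sum(resid**2))
        self._edf = None
        self._leverage = None
        return self

    def predict(self, X) -> np.ndarray:
        return self.spline_(np.asarray(X, dtype=float))

    def derivative(self, X, order: int = 1) -> np.ndarray:
        return self.spline_.derivative(order)(np.asarray(X, dtype=float))

    def _hat_diag(self) -> np.ndarray:
        if self._leverage is None:
            lam = None if self.lam_ == "gcv" else self.lam_
            diag = np.empty(len(self._ux))
            for j in range(len(self._ux)):
                e = np.zeros(len(self._ux))
                e[j] = 1.0
                diag[j] = self._fit_spline(self._ux, e, self._w, lam)(self._ux[j])
            self._leverage = diag
        return self._leverage

    @property
    def effective_df(self) -> float:
        """Trace of the smoother (hat) matrix on the pooled abscissae."""
        if self._edf is None:
            self._edf = float(np.sum(self._hat_diag()))
        return self._edf

    def residual_variance(self) -> float:
        df = max(self.n_obs_ - self.effective_df, 1.0)
        return self._rss / df

    def confidence_band(self, X, level: float = 0.95):
        """Pointwise normal band from the hat-diagonal leverage."""
        from scipy import stats

        lev = np.interp(
            np.asarray(X, dtype=float), self._ux, np.maximum(self._hat_diag(), 0.0)
        )
        se = np.sqrt(self.residual_variance() * lev / np.maximum(self._w.mean(), 1.0))
        z = stats.norm.ppf(0.5 + level / 2.0)
        mu = self.predict(X)
        return mu - z * se, mu + z * se


@dataclass
class PopulationCurve:
    """Fitted mean volume-age curve for one ROI and subject group."""

    roi: str
    group: object
    smoother: SmoothingSplineRegressor
    age_range: tuple[float, float]
    n_obs: int
    meta: dict = field(default_factory=dict)

    def mean(self, ages) -> np.ndarray:
        return self.smoother.predict(ages)

    def band(self, ages, level: float = 0.95):
        return self.smoother.confidence_band(ages, level)

    def derivative(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        lo, hi = self.age_range
        if (ages < lo - 1e-9).any() or (ages > hi + 1e-9).any():
            raise ValueError(
                f"rate of change requested outside fitted range [{lo:.2f}, {hi:.2f}]"
            )
        return self.smoother.derivative(ages)

    @property
    def effective_df(self) -> float:
        return self.smoother.effective_df

    def to_frame(self, ages) -> pd.DataFrame:
        lo_b, hi_b = self.band(ages)
        return pd.DataFrame(
            {
                "age": ages,
                "mean": self.mean(ages),
                "low": lo_b,
                "high": hi_b,
                "derivative": self.derivative(ages),
            }
        )


def fit_population_curve(
    cohort: Cohort,
    roi: str,
    group_labels: pd.Series | None = None,
    lam="gcv",
    trajectory_model: ROITrajectoryLMM | None = None,
    absorb_random_effects: bool = True,
    min_group_obs: int = 50,
) -> dict[object, PopulationCurve]:
    """Fit the smooth mean volume-age curve per group.

    Volumes are adjusted for the trajectory model's covariate effects and
    for within-group individual random effects (BLUP removal with the
    group-mean random-effect trend added back), then smoothed over age.
    """
    df = cohort.data
    if group_labels is None:
        groups = pd.Series("all", index=df.index)
    else:
        groups = df["subject_id"].map(group_labels)

    if absorb_random_effects:
        model = trajectory_model or ROITrajectoryLMM(roi=roi).fit(cohort)
        s = model.age_transform(df["age"])
        b0 = df["subject_id"].map(model.blups_["b0"]).to_numpy()
        b1 = df["subject_id"].map(model.blups_["b1"]).to_numpy()
        indiv = b0 + b1 * s
        pop = model.population_prediction(df["age"])
        if model.n_obs_ == len(df):
            # covariate adjustment: fixed-effect design fit minus the age-only part
            fixed = model._model.exog @ model.fixed_coefficients_.to_numpy()
            cov_part = fixed - np.asarray(pop)
        else:
            cov_part = np.zeros(len(df))
        y_adj = df[roi].to_numpy(dtype=float) - cov_part - indiv
        # keep the group-average random-effect trend so contrasts survive
        for g in groups.unique():
            m = (groups == g).to_numpy()
            subj = df.loc[m, "subject_id"].unique()
            gb0 = model.blups_.loc[subj, "b0"].mean()
            gb1 = model.blups_.loc[subj, "b1"].mean()
            y_adj[m] = y_adj[m] + gb0 + gb1 * np.asarray(s)[m]
    else:
        y_adj = df[roi].to_numpy(dtype=float)

    curves: dict[object, PopulationCurve] = {}
    for g in groups.unique():
        m = (groups == g).to_numpy()
        if m.sum() < min_group_obs:
            raise ValueError(f"group {g!r} has fewer than {min_group_obs} observations")
        ages = df.loc[m, "age"].to_numpy(dtype=float)
        if np.ptp(ages) == 0:
            raise DegenerateInputError(f"group {g!r} has no age spread")
        smoother = SmoothingSplineRegressor(lam=lam).fit(ages, y_adj[m])
        curves[g] = PopulationCurve(
            roi=roi,
            group=g,
            smoother=smoother,
            age_range=(float(ages.min()), float(ages.max())),
            n_obs=int(m.sum()),
        )
    return curves


def curve_rate_of_change(curve: PopulationCurve, ages) -> pd.DataFrame:
    """Analytic dmu/dage (mm^3/year) with a pointwise band."""
    ages = np.asarray(ages, dtype=float)
    deriv = curve.derivative(ages)
    return pd.DataFrame({"age": ages, "rate": deriv})
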