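"""Per-ROI linear mixed models for longitudinal volume trajectories.

The population trajectory of each ROI is a quadratic in age with additive
covariate effects (sex, site, handedness, ethnicity, ICV); each subject
carries a random intercept and, by default, a random age slope with an
unstructured 2x2 covariance.  Estimation is by REML (statsmodels MixedLM).
Subject-level deviations from the population average at a reference age
(default 60 y) are the best linear unbiased predictors (BLUPs)

    d_i(a*) = b0_i + b1_i * s(a*),

with s the model's affine age transform (centered at the sample mean age
and divided by 10 for conditioning of the quadratic term).  Deviations are
covariate-free by construction: the fixed part cancels.  Adding d_i(a*) to
the population fixed-effect prediction at a* yields the individualized
total-volume phenotype used for genetic association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM

from .cohort import Cohort
from .exceptions import ConvergenceError

__all__ = [
    "ROITrajectoryLMM",
    "ModelComparison",
    "DeviationMatrix",
    "fit_roi_lmm",
    "compare_random_structures",
    "fit_deviation_matrix",
    "estimate_total_gmv_at_age",
    "gls_blups",
]

DEFAULT_COVARIATES = ("sex", "site", "handedness", "ethnicity", "icv")


@dataclass
class DeviationMatrix:
    """Subjects x ROIs matrix of deviations at a common reference age."""

    data: pd.DataFrame
    reference_age: float

    def to_tsv(self, path) -> None:
        self.data.rename_axis("subject_id").to_csv(path, sep="\t")


@dataclass
class ModelComparison:
    roi: str
    aic_ri: float
    aic_ris: float
    bic_ri: float
    bic_ris: float
    icc_ri: float
    preferred: str  # "RI" or "RIS"


def _as_frame(cohort) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, Cohort) else cohort


class ROITrajectoryLMM(BaseEstimator):
    """Mixed model for one ROI: quadratic fixed age trend, random intercept
    and (optionally) random age slope.

    Parameters
    ----------
    roi : outcome column (a regional volume or ``"tgmv"``).
    random_slope : include a per-subject age slope with unstructured
        intercept-slope covariance.
    covariates : fixed-effect adjustment columns; categorical columns are
        treatment-coded, ``icv`` enters centered.
    age_scale : divisor of centered age; 10 keeps the quadratic term
        well conditioned over a ~40-year age span.
    reml : restricted maximum likelihood (unbiased variance components);
        set False for likelihood-based model comparison.

    Attributes (after ``fit``)
    ----------
    fixed_coefficients_ : fixed-effect estimates (scaled-age metric).
    cov_re_ : random-effect covariance (data units, scaled-age metric).
    sigma2_e_ : residual variance.
    blups_ : per-subject (b0, b1) best linear unbiased predictors.
    age_mean_, age_span_ : the affine age transform and observed span.
    """

    def __init__(
        self,
        roi: str = "tgmv",
        random_slope: bool = True,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        age_scale: float = 10.0,
        reml: bool = True,
    ):
        self.roi = roi
        self.random_slope = random_slope
        self.covariates = covariates
        self.age_scale = age_scale
        self.reml = reml

    # -- age transform ---------------------------------------------------
    def age_transform(self, age) -> np.ndarray:
        return (np.asarray(age, dtype=float) - self.age_mean_) / self.age_scale

    def _prepare(self, df: pd.DataFrame) -> pd.DataFrame:
        d = df.dropna(subset=[self.roi]).copy()
        self.age_mean_ = float(d["age"].mean())
        self.age_span_ = (float(d["age"].min()), float(d["age"].max()))
        d["age_c"] = self.age_transform(d["age"])
        d["age_c2"] = d["age_c"] ** 2
        if "icv" in self.covariates:
            d["icv_c"] = d["icv"] - d["icv"].mean()
        return d

    def _formula(self) -> str:
        terms = ["age_c", "age_c2"]
        for cov in self.covariates:
            if cov == "icv":
                terms.append("icv_c")
            else:
                terms.append(f"C({cov})")
        return f"{self.roi} ~ " + " + ".join(terms)

    # -- fitting ---------------------------------------------------------
    def fit(self, cohort, start_params=None) -> "ROITrajectoryLMM":
        """Fit the mixed model.  ``start_params`` (a fitted parameter object
        from a comparable model) warm-starts the optimizer; useful when
        fitting many ROIs of similar structure."""
        df = _as_frame(cohort)
        if df["subject_id"].nunique() < 30:
            raise ValueError("need at least 30 subjects for a stable mixed fit")
        d = self._prepare(df)
        re_formula = "~age_c" if self.random_slope else "~1"
        model = MixedLM.from_formula(
            self._formula(), data=d, groups=d["subject_id"], re_formula=re_formula
        )
        self._check_rank(model)
        if self._try_degenerate_fit(model, d):
            return self
        # standardize the outcome for the optimizer; mm^3-scale volumes put
        # variance components near 1e9 and break gradient tolerances
        y_sd = float(np.std(model.endog)) or 1.0
        d = d.copy()
        d[self.roi] = d[self.roi] / y_sd
        model = MixedLM.from_formula(
            self._formula(), data=d, groups=d["subject_id"], re_formula=re_formula
        )
        result = None
        trace: list[str] = []
        for method in ("lbfgs", "powell", "bfgs"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cand = model.fit(
                        reml=self.reml,
                        method=method,
                        maxiter=500,
                        start_params=start_params,
                    )
                except Exception as exc:  # noqa: BLE001 - recorded in trace
                    trace.append(f"{method}: raised {exc!r}")
                    continue
            if cand.converged:
                result = cand
                break
            trace.append(f"{method}: no convergence")
        if result is None:
            raise ConvergenceError(
                f"mixed model for {self.roi!r} failed to converge; trace: {trace}"
            )
        self.result_ = result
        self.converged_ = bool(result.converged)
        self.fixed_coefficients_ = result.fe_params * y_sd
        self.cov_re_ = np.atleast_2d(np.asarray(result.cov_re)) * y_sd**2
        self.sigma2_e_ = float(result.scale) * y_sd**2
        n, p = int(model.nobs), model.exog.shape[1]
        dof = n - p if self.reml else n
        self.log_likelihood_ = float(result.llf) - dof * np.log(y_sd)
        self.n_obs_ = n
        re = pd.DataFrame(result.random_effects).T * y_sd
        re.columns = ["b0", "b1"] if self.random_slope else ["b0"]
        if not self.random_slope:
            re["b1"] = 0.0
        re.index.name = "subject_id"
        self.blups_ = re
        self._y_sd = y_sd
        self._model = model
        self.params_object_ = getattr(result, "params_object", None)
        return self

    def _try_degenerate_fit(self, model, d) -> bool:
        """Short-circuit for (near-)noiseless data: an exact OLS fit means
        all variance components are 0 and the likelihood surface is
        degenerate, so report the OLS solution with zero BLUPs."""
        X, y = model.exog, model.endog
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        scale = float(np.var(y)) or 1.0
        if float(np.mean(resid**2)) > 1e-16 * scale:
            return False
        self.result_ = None
        self.converged_ = True
        self.fixed_coefficients_ = pd.Series(beta, index=model.exog_names)
        k = 2 if self.random_slope else 1
        self.cov_re_ = np.zeros((k, k))
        self.sigma2_e_ = float(np.mean(resid**2))
        self.log_likelihood_ = np.inf
        self.n_obs_ = int(model.nobs)
        subjects = pd.Index(pd.unique(model.groups), name="subject_id")
        self.blups_ = pd.DataFrame(0.0, index=subjects, columns=["b0", "b1"])
        self._model = model
        return True

    def _check_rank(self, model) -> None:
        X = model.exog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, r = np.linalg.qr(X)
            bad = np.asarray(model.exog_names)[np.abs(np.diag(r)) < 1e-8]
            raise np.linalg.LinAlgError(
                f"rank-deficient fixed-effect design; collinear columns: {list(bad)}"
            )

    # -- derived quantities ---------------------------------------------
    def deviation_at_age(self, reference_age: float = 60.0) -> pd.Series:
        """Subject deviations d_i(a*) = b0_i + b1_i * s(a*)."""
        lo, hi = self.age_span_
        half = (hi - lo) / 2.0
        center = (hi + lo) / 2.0
        if abs(reference_age - center) > 1.5 * half:
            warnings.warn(
                f"reference age {reference_age} lies outside 1.5x the observed "
                f"age span [{lo:.1f}, {hi:.1f}]",
                stacklevel=2,
            )
        s = float(self.age_transform(reference_age))
        d = self.blups_["b0"] + self.blups_["b1"] * s
        return d.rename(f"deviation@{reference_age:g}")

    def population_prediction(self, age) -> np.ndarray:
        """Fixed-effect prediction at reference covariate levels."""
        s = self.age_transform(age)
        fe = self.fixed_coefficients_
        return fe["Intercept"] + fe["age_c"] * s + fe["age_c2"] * s**2

    def phenotype_at_age(self, reference_age: float = 60.0) -> pd.Series:
        """Population prediction at a* plus each subject's deviation."""
        pred = float(self.population_prediction(reference_age))
        return (pred + self.deviation_at_age(reference_age)).rename(
            f"phenotype@{reference_age:g}"
        )

    def blups_at(self, cov_re: np.ndarray, sigma2_e: float) -> pd.DataFrame:
        """BLUPs (and GLS fixed effects) at externally fixed variance
        components, via the mixed-model normal equations per subject."""
        model = self._model
        Z = model.exog_re if self.random_slope else np.ones((int(model.nobs), 1))
        y_sd = getattr(self, "_y_sd", 1.0)
        beta, blups = gls_blups(
            np.asarray(model.endog) * y_sd,
            model.exog,
            Z,
            np.asarray(model.groups),
            np.atleast_2d(np.asarray(cov_re, dtype=float)),
            float(sigma2_e),
        )
        cols = ["b0", "b1"] if self.random_slope else ["b0"]
        out = pd.DataFrame(
            blups, columns=cols, index=pd.Index(pd.unique(model.groups), name="subject_id")
        )
        return out


def gls_blups(y, X, Z, groups, G, sigma2):
    """GLS fixed effects and per-subject BLUPs at fixed (G, sigma2).

    Solves beta = (sum X_i' V_i^-1 X_i)^-1 sum X_i' V_i^-1 y_i with
    V_i = Z_i G Z_i' + sigma2 I, then b_i = G Z_i' V_i^-1 (y_i - X_i beta).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    uniq = pd.unique(groups)
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    xtvy = np.zeros(X.shape[1])
    slices = {g: np.flatnonzero(groups == g) for g in uniq}
    vinv = {}
    for g, idx in slices.items():
        Zi = Z[idx]
        Vi = Zi @ G @ Zi.T + sigma2 * np.eye(len(idx))
        Vi_inv = np.linalg.inv(Vi)
        vinv[g] = Vi_inv
        Xi = X[idx]
        xtvx += Xi.T @ Vi_inv @ Xi
        xtvy += Xi.T @ Vi_inv @ y[idx]
    beta = np.linalg.solve(xtvx, xtvy)
    blups = np.empty((len(uniq), G.shape[0]))
    for j, g in enumerate(uniq):
        idx = slices[g]
        resid = y[idx] - X[idx] @ beta
        blups[j] = G @ Z[idx].T @ vinv[g] @ resid
    return beta, blups


# ----------------------------------------------------------------------
# module-level wrappers


def fit_roi_lmm(
    cohort, roi: str, include_random_slope: bool = True, **kwargs
) -> ROITrajectoryLMM:
    return ROITrajectoryLMM(roi=roi, random_slope=include_random_slope, **kwargs).fit(
        cohort
    )


def compare_random_structures(cohort, roi: str, **kwargs) -> ModelComparison:
    """AIC/BIC comparison of random-intercept vs random-intercept+slope.

    Both candidates are fit by ML so the criteria share one likelihood
    convention; the intra-class correlation comes from the RI model.
    """
    ri = ROITrajectoryLMM(roi=roi, random_slope=False, reml=False, **kwargs).fit(cohort)
    ris = ROITrajectoryLMM(roi=roi, random_slope=True, reml=False, **kwargs).fit(cohort)
    icc = float(ri.cov_re_[0, 0] / (ri.cov_re_[0, 0] + ri.sigma2_e_))

    def _criteria(m, n_vc):
        k = len(m.fixed_coefficients_) + n_vc + 1  # + residual variance
        aic = 2 * k - 2 * m.log_likelihood_
        bic = k * np.log(m.n_obs_) - 2 * m.log_likelihood_
        return float(aic), float(bic)

    aic_ri, bic_ri = _criteria(ri, 1)
    aic_ris, bic_ris = _criteria(ris, 3)
    return ModelComparison(
        roi=roi,
        aic_ri=aic_ri,
        aic_ris=aic_ris,
        bic_ri=bic_ri,
        bic_ris=bic_ris,
        icc_ri=icc,
        preferred="RI" if aic_ri <= aic_ris else "RIS",
    )


def fit_deviation_matrix(
    cohort,
    rois=None,
    reference_age: float = 60.0,
    random_slope: bool = True,
    **kwargs,
) -> tuple[DeviationMatrix, dict[str, ROITrajectoryLMM]]:
    """Fit one mixed model per ROI and collect deviations at ``reference_age``."""
    if rois is None:
        rois = list(cohort.roi_columns)
    cols = {}
    models = {}
    warm = None
    for roi in rois:
        m = ROITrajectoryLMM(roi=roi, random_slope=random_slope, **kwargs).fit(
            cohort, start_params=warm
        )
        warm = getattr(m, "params_object_", None)
        cols[roi] = m.deviation_at_age(reference_age)
        models[roi] = m
    mat = pd.DataFrame(cols)
    mat.index.name = "subject_id"
    return DeviationMatrix(mat, reference_age), models


def estimate_total_gmv_at_age(
    model_tgmv: ROITrajectoryLMM, reference_age: float = 60.0
) -> pd.Series:
    """Individualized total-GMV phenotype (the genetic-association trait)."""
    return model_tgmv.phenotype_at_age(reference_age)
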