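"""Group contrasts between brain-aging patterns.

Compares any subject-level measure (aging biomarkers, cognitive scores,
polygenic scores) between pattern 1 and pattern 2 with the conventional
effect sizes: Cohen's D (pooled-SD, pattern-2-minus-pattern-1 so negative
values mean worse in the faster-declining pattern) for continuous
measures, odds ratios with Woolf logit intervals for binary ones, and
covariate-adjusted variants via linear or logistic regression.  Family-wise
adjustment is Bonferroni or Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError

__all__ = [
    "ContrastResult",
    "cohens_d",
    "odds_ratio",
    "adjusted_group_contrast",
    "adjust_pvalues",
    "contrast_table",
]


@dataclass
class ContrastResult:
    measure: str
    effect: float
    effect_type: str            # "cohens_d" or "odds_ratio"
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float | None = None
    adjustment_set: tuple[str, ...] = ()
    method: str | None = None
    note: str | None = None


def cohens_d(values_group1, values_group2) -> tuple[float, tuple[float, float]]:
    """Pooled-SD Cohen's D, group 2 minus group 1, with a 95% CI.

    The CI uses the standard large-sample variance of D.
    """
    x1 = np.asarray(values_group1, dtype=float)
    x2 = np.asarray(values_group2, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    n1, n2 = len(x1), len(x2)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 finite values")
    s2p = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2p == 0:
        raise DegenerateInputError("pooled SD is zero")
    d = (x2.mean() - x1.mean()) / np.sqrt(s2p)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    z = stats.norm.ppf(0.975)
    return float(d), (float(d - z * se), float(d + z * se))


def odds_ratio(
    table: np.ndarray, continuity: bool = True
) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio of a 2x2 count table with a Woolf 95% CI.

    Rows are groups, columns outcome (event, non-event).  A 0.5 continuity
    correction is applied when any cell is zero (if ``continuity``).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero margin in 2x2 table")
    if (t == 0).any():
        if not continuity:
            raise DegenerateInputError("zero cell without continuity correction")
        t = t + 0.5
    orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = np.sqrt((1.0 / t).sum())
    z = stats.norm.ppf(0.975)
    return float(orr), (float(np.exp(np.log(orr) - z * se)), float(np.exp(np.log(orr) + z * se)))


def adjusted_group_contrast(
    outcome: pd.Series,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
    measure: str = "outcome",
    binary: bool | None = None,
) -> ContrastResult:
    """Covariate-adjusted contrast of ``outcome`` between patterns 1 and 2.

    Continuous outcomes: linear regression; the group-2 coefficient divided
    by the residual SD gives the adjusted Cohen's D.  Binary outcomes:
    logistic regression; the exponentiated coefficient gives the adjusted
    odds ratio.  Group coding follows pattern-2-minus-pattern-1.
    """
    df = pd.DataFrame({"y": outcome, "g": group})
    if covariates is not None:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    y = df.pop("y").to_numpy(dtype=float)
    g2 = (df.pop("g") == 2).astype(float).to_numpy()
    X = sm.add_constant(
        np.column_stack([g2, df.to_numpy(dtype=float)]) if df.shape[1] else g2
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    z = stats.norm.ppf(0.975)
    if binary:
        note = None
        try:
            res = sm.Logit(y, X).fit(disp=False)
            if not res.mle_retvals.get("converged", True):
                raise np.linalg.LinAlgError("no convergence")
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            # separation fallback: small ridge penalty keeps estimates finite
            res = sm.Logit(y, X).fit_regularized(alpha=1e-3, disp=False)
            note = "penalized fit (separation)"
        beta = res.params[1]
        se = res.bse[1] if hasattr(res, "bse") else np.nan
        p = res.pvalues[1] if hasattr(res, "pvalues") else np.nan
        return ContrastResult(
            measure=measure,
            effect=float(np.exp(beta)),
            effect_type="odds_ratio",
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p=float(p),
            adjustment_set=tuple(covariates.columns) if covariates is not None else (),
            note=note,
        )
    res = sm.OLS(y, X).fit()
    resid_sd = np.sqrt(res.mse_resid)
    d = res.params[1] / resid_sd
    se_d = res.bse[1] / resid_sd
    return ContrastResult(
        measure=measure,
        effect=float(d),
        effect_type="cohens_d",
        ci_low=float(d - z * se_d),
        ci_high=float(d + z * se_d),
        p=float(res.pvalues[1]),
        adjustment_set=tuple(covariates.columns) if covariates is not None else (),
    )


def adjust_pvalues(p_list, method: str = "fdr_bh") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(list(p_list), dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bonferroni": "bonferroni", "fdr_bh": "fdr_bh", "bh": "fdr_bh"}[method.lower()]
    return multipletests(p, method=key)[1]


def contrast_table(results: list[ContrastResult], method: str = "fdr_bh") -> pd.DataFrame:
    """Assemble contrasts into one table with family-wise adjusted p."""
    adj = adjust_pvalues([r.p for r in results], method=method)
    rows = []
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.method = method
        rows.append(
            {
                "measure": r.measure,
                "effect_type": r.effect_type,
                "effect": r.effect,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
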