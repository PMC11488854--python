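"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of population neuroimaging cohorts: an
adult cohort (ages 44-82, mostly single scans with ~10% follow-up, matching
a 36,914-baseline / 4,007-follow-up design) and an adolescent cohort (ages
~14-23, 2-3 scans each).  Per-ROI volumes follow a quadratic mean age trend
plus additive covariate effects, a per-subject bivariate-normal random
intercept/slope, an optional planted two-pattern mixture (pattern 2 has a
lower baseline volume and a faster decline), and i.i.d. Gaussian noise:

    V_ir(t) = beta0_r + beta1_r t + beta2_r t^2 + covariates
              + 1{pattern 2}(delta0_r + delta1_r t)
              + b0_ir + b1_ir t + eps_irt,       t = age - age_center.

Ground truth (labels, random effects, offsets) is returned alongside so
every downstream stage has a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ..cohort import CORTICAL_ROIS, DEFAULT_ROIS, Cohort
from ..exceptions import ConfigurationError

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "adult_config",
    "adolescent_config",
    "generate_longitudinal_cohort",
    "generate_mirrored_cohorts",
    "baseline_volume_sd",
]


def _default_base_volumes(rois: tuple[str, ...]) -> np.ndarray:
    # Deterministic plausible mean volumes (mm^3), spread over the
    # range of bilaterally averaged DK parcels / ASEG structures.
    n = len(rois)
    return 4000.0 + 14000.0 * (np.arange(n) % 7) / 6.0 + 500.0 * (np.arange(n) % 5)


@dataclass
class CohortConfig:
    """Generative settings for one longitudinal cohort.

    Volumes scale with ``base_volumes`` (per-ROI mean volume at the cohort
    age center); variance components and effect sizes are expressed as
    fractions of that base volume so one set of defaults serves every ROI.
    """

    n_subjects: int = 2000
    age_range: tuple[float, float] = (44.0, 82.0)
    #: visit-count distribution, e.g. {1: 0.9, 2: 0.1}
    visit_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.9, 2: 0.1}
    )
    #: inter-visit gap drawn uniformly from this range (years)
    visit_gap_range: tuple[float, float] = (4.0, 6.0)
    #: proportion of pattern-2 (faster-declining) subjects
    pattern_mixing: float = 0.0
    #: pattern-2 intercept offset, units of baseline-volume SD (negative = lower)
    pattern_intercept_shift: float = -0.5
    #: pattern-2 slope offset, units of the slope SD (negative = faster decline)
    pattern_slope_shift: float = -0.3
    rois: tuple[str, ...] = DEFAULT_ROIS
    base_volumes: np.ndarray | None = None
    #: fractional annual rate of change at the age center (per ROI or scalar)
    decline_rate: float | np.ndarray = -0.004
    #: fractional quadratic age coefficient (decline accelerates when < 0)
    curvature: float | np.ndarray = -5e-5
    rel_sigma_b0: float = 0.10       # random-intercept SD / base volume
    rel_sigma_b1: float = 0.0015     # random-slope SD / base volume (per year)
    re_correlation: float = -0.2     # corr(b0, b1)
    rel_sigma_e: float = 0.025       # residual SD / base volume
    rel_sex_effect: float = 0.04
    rel_site_effect: float = 0.01
    rel_handedness_effect: float = 0.005
    rel_ethnicity_effect: float = 0.008
    #: ROI-volume SD attributable to ICV, as fraction of base volume
    rel_icv_effect: float = 0.12
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    n_sites: int = 3
    n_ethnicities: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_volumes is None:
            self.base_volumes = _default_base_volumes(tuple(self.rois))
        self.base_volumes = np.asarray(self.base_volumes, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.pattern_mixing <= 1.0:
            raise ConfigurationError(
                f"pattern_mixing must be in [0, 1], got {self.pattern_mixing}"
            )
        for name in ("rel_sigma_b0", "rel_sigma_b1", "rel_sigma_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(self.re_correlation) > 1:
            raise ConfigurationError("|re_correlation| must be <= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        probs = np.array(list(self.visit_count_probs.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("visit_count_probs must be a distribution")
        if min(self.visit_count_probs) < 1:
            raise ConfigurationError("visit counts must be >= 1")
        if len(self.base_volumes) != len(self.rois):
            raise ConfigurationError("base_volumes length must match rois")
        glo, ghi = self.visit_gap_range
        if not 0 < glo <= ghi:
            raise ConfigurationError("visit_gap_range must be positive and ordered")
        max_span = ghi * (max(self.visit_count_probs) - 1)
        if max_span >= hi - lo:
            raise ConfigurationError("visit schedule cannot fit inside age_range")

    @property
    def age_center(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class CohortTruth:
    """Ground truth for one generated cohort (plumbing for recovery tests)."""

    labels: pd.Series                 # subject -> {1, 2}
    b0: pd.DataFrame                  # subjects x ROIs random intercepts
    b1: pd.DataFrame                  # subjects x ROIs random slopes
    delta0: pd.Series                 # ROI -> pattern-2 intercept offset (mm^3)
    delta1: pd.Series                 # ROI -> pattern-2 slope offset (mm^3/yr)
    age_center: float
    pattern_mixing: float

    def _centered_indicator(self) -> pd.Series:
        return (self.labels == 2).astype(float) - self.pattern_mixing

    def total_deviation(self, age: float) -> pd.Series:
        """True TGMV deviation from the population mean at ``age``."""
        z2 = self._centered_indicator()
        t = age - self.age_center
        b0_tot = self.b0.sum(axis=1) + z2 * self.delta0.sum()
        b1_tot = self.b1.sum(axis=1) + z2 * self.delta1.sum()
        return b0_tot + b1_tot * t

    def roi_deviation(self, roi: str, age: float) -> pd.Series:
        z2 = self._centered_indicator()
        t = age - self.age_center
        return (self.b0[roi] + z2 * self.delta0[roi]) + (
            self.b1[roi] + z2 * self.delta1[roi]
        ) * t

    def to_json_dict(self) -> dict:
        return {
            "labels": self.labels.to_dict(),
            "delta0": self.delta0.to_dict(),
            "delta1": self.delta1.to_dict(),
            "age_center": self.age_center,
            "pattern_mixing": self.pattern_mixing,
            "b0_total": self.b0.sum(axis=1).to_dict(),
            "b1_total": self.b1.sum(axis=1).to_dict(),
        }


def adult_config(**overrides) -> CohortConfig:
    """Mid-to-late adulthood cohort: ages 44-82, ~10% with a follow-up scan."""
    return CohortConfig(**overrides)


def adolescent_config(**overrides) -> CohortConfig:
    """Adolescent cohort: ages ~13.5-23, 2-3 scans per subject."""
    defaults = dict(
        n_subjects=400,
        age_range=(13.5, 23.0),
        visit_count_probs={2: 0.6, 3: 0.4},
        visit_gap_range=(2.0, 3.5),
        decline_rate=-0.008,
        curvature=0.0,
        pattern_mixing=0.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def baseline_volume_sd(config: CohortConfig) -> np.ndarray:
    """Approximate analytic SD of baseline ROI volume across subjects.

    Sums the dominant cross-sectional variance components: random
    intercept, ICV scaling, the age trend over the baseline-age spread,
    sex, and measurement noise.  Used to express planted pattern offsets
    in population-SD units.
    """
    v = config.base_volumes
    lo, hi = config.age_range
    age_var = (hi - lo) ** 2 / 12.0
    beta1 = np.broadcast_to(np.asarray(config.decline_rate, float) * v, v.shape)
    var = (
        (config.rel_sigma_b0 * v) ** 2
        + (config.rel_icv_effect * v) ** 2
        + beta1**2 * age_var
        + (config.rel_sex_effect * v) ** 2 * 0.25
        + (config.rel_sigma_e * v) ** 2
    )
    return np.sqrt(var)


def _draw_visit_ages(config: CohortConfig, n_visits: np.ndarray, rng) -> list[np.ndarray]:
    lo, hi = config.age_range
    glo, ghi = config.visit_gap_range
    ages = []
    for k in n_visits:
        gaps = rng.uniform(glo, ghi, size=k - 1)
        span = gaps.sum()
        base = rng.uniform(lo, hi - span)
        ages.append(base + np.concatenate([[0.0], np.cumsum(gaps)]))
    return ages


def generate_longitudinal_cohort(
    config: CohortConfig,
) -> tuple[Cohort, CohortTruth]:
    """Generate a long-format visit table plus its ground truth.

    Deterministic given ``config.seed``: every sub-generator derives a
    child seed from one global ``SeedSequence``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (s_cov, s_visits, s_re, s_noise, s_label) = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]

    n = config.n_subjects
    rois = list(config.rois)
    p = len(rois)
    v = config.base_volumes

    subjects = np.array([f"S{idx:06d}" for idx in range(n)])
    labels = np.where(s_label.random(n) < config.pattern_mixing, 2, 1)

    sex = s_cov.integers(0, 2, size=n)
    site = s_cov.integers(0, config.n_sites, size=n)
    handedness = np.where(s_cov.random(n) < 0.9, 0, 1)
    ethnicity = s_cov.integers(0, config.n_ethnicities, size=n)
    icv = s_cov.normal(config.icv_mean, config.icv_sd, size=n)

    counts = np.array(sorted(config.visit_count_probs))
    probs = np.array([config.visit_count_probs[c] for c in counts], dtype=float)
    n_visits = s_visits.choice(counts, size=n, p=probs)
    visit_ages = _draw_visit_ages(config, n_visits, s_visits)

    # bivariate-normal random effects, independent across ROIs
    sigma_b0 = config.rel_sigma_b0 * v
    sigma_b1 = config.rel_sigma_b1 * v
    rho = config.re_correlation
    z = s_re.standard_normal((2, n, p))
    b0 = sigma_b0 * z[0]
    b1 = sigma_b1 * (rho * z[0] + np.sqrt(max(0.0, 1 - rho**2)) * z[1])

    base_sd = baseline_volume_sd(config)
    delta0 = config.pattern_intercept_shift * base_sd
    delta1 = config.pattern_slope_shift * sigma_b1

    beta1 = np.broadcast_to(np.asarray(config.decline_rate, float) * v, v.shape)
    beta2 = np.broadcast_to(np.asarray(config.curvature, float) * v, v.shape)
    gamma_icv = config.rel_icv_effect * v / config.icv_sd

    sex_eff = config.rel_sex_effect * v
    site_eff = config.rel_site_effect * v
    hand_eff = config.rel_handedness_effect * v
    ethn_eff = config.rel_ethnicity_effect * v

    rows = []
    vol_blocks = []
    is2 = (labels == 2).astype(float)
    for i in range(n):
        t = visit_ages[i] - config.age_center
        k = len(t)
        fixed = (
            v[None, :]
            + beta1[None, :] * t[:, None]
            + beta2[None, :] * t[:, None] ** 2
            + sex_eff[None, :] * sex[i]
            + site_eff[None, :] * (site[i] - (config.n_sites - 1) / 2.0)
            + hand_eff[None, :] * handedness[i]
            + ethn_eff[None, :] * (ethnicity[i] - (config.n_ethnicities - 1) / 2.0)
            + gamma_icv[None, :] * (icv[i] - config.icv_mean)
        )
        pattern = is2[i] * (delta0[None, :] + delta1[None, :] * t[:, None])
        random_part = b0[i][None, :] + b1[i][None, :] * t[:, None]
        noise = s_noise.standard_normal((k, p)) * (config.rel_sigma_e * v)[None, :]
        vol_blocks.append(fixed + pattern + random_part + noise)
        for j in range(k):
            rows.append(
                (
                    subjects[i], j, visit_ages[i][j], sex[i], site[i],
                    handedness[i], ethnicity[i], icv[i],
                )
            )

    meta = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "visit", "age", "sex", "site",
            "handedness", "ethnicity", "icv",
        ],
    )
    vols = pd.DataFrame(np.vstack(vol_blocks), columns=rois)
    meta["tgmv"] = vols.sum(axis=1)
    data = pd.concat([meta, vols], axis=1)

    idx = pd.Index(subjects, name="subject_id")
    truth = CohortTruth(
        labels=pd.Series(labels, index=idx, name="pattern"),
        b0=pd.DataFrame(b0, index=idx, columns=rois),
        b1=pd.DataFrame(b1, index=idx, columns=rois),
        delta0=pd.Series(delta0, index=pd.Index(rois, name="roi")),
        delta1=pd.Series(delta1, index=pd.Index(rois, name="roi")),
        age_center=config.age_center,
        pattern_mixing=config.pattern_mixing,
    )
    return Cohort(data, tuple(rois)), truth


def generate_mirrored_cohorts(
    n_dev: int = 300,
    n_age: int = 300,
    n_lifo: int = 3,
    seed: int = 0,
    rois: tuple[str, ...] = CORTICAL_ROIS,
):
    """Development/aging cohort pair with planted opposite ROI rankings.

    The ``n_lifo`` planted "last in, first out" ROIs decline slowest during
    development and fastest during aging; the remaining ROIs' aging rates
    are negatively coupled to their development rates, so the standardized
    development and aging maps have negative rank correlation by design.

    Returns (dev_cohort, age_cohort, truth) where truth holds the planted
    ROI names and the two fractional annual-rate profiles (in %/yr).
    """
    ss = np.random.SeedSequence(seed)
    s_prof, s_dev, s_age = ss.spawn(3)
    rng = np.random.default_rng(s_prof)
    p = len(rois)

    # Planted effect magnitudes are chosen so the ROI ranking stays
    # resolvable at desk-scale cohort sizes: the between-ROI spread is wide
    # relative to the curve-evaluation noise a few hundred two-scan
    # subjects leave, mimicking the separation a full-scale cohort affords.
    lifo_idx = rng.choice(p, size=n_lifo, replace=False)
    dev_apc = rng.uniform(-1.8, -0.6, size=p)
    dev_apc[lifo_idx] = rng.uniform(-0.12, -0.04, size=n_lifo)
    zdev = (dev_apc - dev_apc.mean()) / dev_apc.std()
    age_apc = -0.7 - 0.5 * zdev + rng.normal(0.0, 0.05, size=p)

    dev_cfg = adolescent_config(
        n_subjects=n_dev,
        rois=rois,
        decline_rate=dev_apc / 100.0,
        curvature=0.0,
        seed=int(np.random.default_rng(s_dev).integers(2**31 - 1)),
    )
    age_cfg = adult_config(
        n_subjects=n_age,
        rois=rois,
        visit_count_probs={2: 1.0},
        decline_rate=age_apc / 100.0,
        curvature=0.0,
        pattern_mixing=0.0,
        seed=int(np.random.default_rng(s_age).integers(2**31 - 1)),
    )
    dev_cohort, _ = generate_longitudinal_cohort(dev_cfg)
    age_cohort, _ = generate_longitudinal_cohort(age_cfg)
    truth = {
        "lifo_rois": [rois[i] for i in lifo_idx],
        "dev_apc": pd.Series(dev_apc, index=list(rois)),
        "age_apc": pd.Series(age_apc, index=list(rois)),
    }
    return dev_cohort, age_cohort, truth
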