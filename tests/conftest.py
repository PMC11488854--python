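import numpy as np
import pandas as pd
import pytest

from neuroaging import synth
from neuroaging.cohort import CORTICAL_ROIS


@pytest.fixture(scope="session")
def small_adult():
    """Adult cohort with planted patterns, small enough for fast fits."""
    cfg = synth.adult_config(n_subjects=300, pattern_mixing=0.5, seed=101)
    return synth.generate_longitudinal_cohort(cfg)


@pytest.fixture(scope="session")
def parcellation():
    return synth.generate_parcellation(seed=7)


@pytest.fixture(scope="session")
def coupled_expression(parcellation):
    """Expression matrix with 5 genes coupled (r=0.9) to a smooth map."""
    rng = np.random.default_rng(11)
    rois = parcellation.cortical_rois()
    from neuroaging.maps import RegionMap

    target = RegionMap(pd.Series(rng.normal(size=len(rois)), index=rois))
    X, truth = synth.generate_expression(
        parcellation,
        n_genes=150,
        smoothness=0.5,
        coupled_map=target,
        n_coupled=5,
        coupling_r=0.9,
        seed=12,
    )
    return X, target, truth


@pytest.fixture
def tiny_cohort_frame():
    """Hand-built 3-subject frame with the mandatory schema."""
    rows = []
    for s, ages in (("A", [50, 55]), ("B", [60]), ("C", [45, 52, 58])):
        for v, a in enumerate(ages):
            rows.append(
                {
                    "subject_id": s,
                    "visit": v,
                    "age": float(a),
                    "sex": 0,
                    "site": 0,
                    "handedness": 0,
                    "ethnicity": 0,
                    "icv": 1.5e6,
                    "tgmv": 6.0e5 - 1e3 * a,
                    "roi_a": 1.0e4 - 10 * a,
                    "roi_b": 2.0e4 - 20 * a,
                }
            )
    return pd.DataFrame(rows)


def assert_frames_equal(a, b):
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
    )
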