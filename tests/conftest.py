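import numpy as np
import pytest

from srbpmri.synthetic import CohortSpec, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A fast, small phantom: single-grid channels, no outliers, no jitter."""
    return PhantomSpec(
        ref_shape=(8, 32, 32),
        ref_spacing=(3.6, 2.4, 2.4),
        channel_spacing={"ADC": (3.6, 2.4, 2.4), "HBV": (3.6, 2.4, 2.4), "T2": (3.6, 2.4, 2.4)},
        channel_offset_mm={"ADC": (0, 0, 0), "HBV": (0, 0, 0), "T2": (0, 0, 0)},
        prostate_semiaxes=(3.0, 9.0, 9.0),
        tumor_semiaxes=(1.4, 3.5, 3.5),
        f_out=0.0,
        roi_jitter_sd=0.0,
        seed=7,
    )


@pytest.fixture
def default_spec():
    return PhantomSpec(seed=11)


@pytest.fixture
def tiny_cohort_spec():
    return CohortSpec(
        n=6,
        grade_counts={0: 2, 1: 1, 2: 1, 3: 1, 5: 1},
        scanner_counts={"Skyra": 4, "Ingenia": 2},
        technique_counts={"SysBx": 3, "MRBx": 3},
        seed=3,
    )


def spd_matrix(rng, scale=1.0):
    """Random symmetric positive-definite 3x3 matrix."""
    A = rng.standard_normal((3, 3))
    return scale * (A @ A.T + 0.5 * np.eye(3))
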