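import numpy as np
import pytest

from imgfpc import (
    CohortSpec,
    FourierBasis,
    ImageSignal,
    center_coefficients,
    fit_coefficients,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """20 images, 24x24, two groups with distinct smooth means."""
    K = 5
    m0 = np.zeros(K * K)
    m1 = np.zeros(K * K)
    m1[3] = 0.8
    spec = CohortSpec(
        n_per_group=(10, 10), H=24, W=24, K=K,
        group_mean_coeffs=(m0, m1), score_sds=(0.3, 0.2),
        noise_sd=0.02, seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture
def centered_coef(small_cohort):
    images, _ = small_cohort
    basis = FourierBasis(5)
    return center_coefficients(fit_coefficients(images, basis)), basis


def random_images(rng, n, H, W):
    return [ImageSignal(values=rng.standard_normal((H, W))) for _ in range(n)]
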