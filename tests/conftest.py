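import numpy as np
import pytest

import ehgpredict as ep


@pytest.fixture(scope="session")
def small_cohort():
    """Six short records (4 term / 2 preterm), artifact-free for speed."""
    params = ep.SynthCohortParams(n_term=4, n_preterm=2, duration_s=90.0,
                                  artifact_rate=0.0, seed=42)
    return ep.gen_cohort(params)


@pytest.fixture(scope="session")
def full_feature_table(small_cohort):
    """All 143 columns extracted with short (30 s) analysis windows."""
    return ep.extract_feature_table(small_cohort, win_s=30.0)


@pytest.fixture(scope="session")
def separable_table():
    """Abstract feature table with 5 strongly informative columns."""
    return ep.gen_feature_table(50, 5, 45, 3.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
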