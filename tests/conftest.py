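import numpy as np
import pandas as pd
import pytest

import airmasld as am


@pytest.fixture(scope="session")
def big_cohort():
    """One n=50,000 synthetic cohort shared by the moment/prevalence checks.

    Returns (participants, exposure, truth, window_means, analysis_cohort,
    cascade) so the expensive generation and window averaging run once.
    """
    cfg = am.SimConfig(n_participants=50_000, seed=20240)
    parts, expo, truth = am.generate_cohort(cfg)
    wide = am.window_average_table(expo, parts, years=3)
    merged = pd.concat([parts, wide], axis=1)
    cohort, cascade = am.apply_exclusions(merged)
    return parts, expo, truth, wide, cohort, cascade


@pytest.fixture(scope="session")
def small_cohort():
    """A fast n=4,000 cohort for interface-level tests."""
    cfg = am.SimConfig(n_participants=4_000, seed=7)
    parts, expo, truth = am.generate_cohort(cfg)
    wide = am.window_average_table(expo, parts, years=3)
    merged = pd.concat([parts, wide], axis=1)
    cohort, cascade = am.apply_exclusions(merged)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
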