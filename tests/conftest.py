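import numpy as np
import pytest

from neoncts.catalog import build_default_catalog, make_spec
from neoncts.synthetic_cohort import CohortConfig, generate_cohort
from neoncts.vitals_io import assign_labels, make_windows


@pytest.fixture(scope="session")
def default_catalog():
    return build_default_catalog()


@pytest.fixture(scope="session")
def small_catalog():
    """A cheap catalog subset for pipeline-shaped tests."""
    specs = []
    for out in ("mean", "sd", "iqr", "p05"):
        specs.append(make_spec("distribution", out))
    specs.append(make_spec("successive_increases", "count"))
    for out in ("slope_per_step", "intercept", "residual_sd"):
        specs.append(make_spec("trend", out))
    specs.append(make_spec("autocorrelation", "ac", lag=1))
    return specs


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 6-patient cohort with short stays, windows labeled, for IO tests."""
    cfg = CohortConfig(n_patients=6, death_fraction=0.34, seed=7,
                       stay_days_mean=4, stay_days_min=3, stay_days_max=6,
                       windows_per_day=4)
    series, outcomes = generate_cohort(cfg)
    windows = []
    for s in series:
        windows.extend(make_windows(s))
    windows = assign_labels(windows, outcomes)
    return cfg, series, outcomes, windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
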