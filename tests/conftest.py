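import numpy as np
import pytest

import afrecur as af


@pytest.fixture(scope="session")
def default_cohort():
    """74-patient cohort under the default study conditions."""
    return af.simulate_cohort(af.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return af.extract_features(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """24-patient cohort with short series, for fast pipeline tests."""
    cfg = af.SyntheticConfig(
        n_patients=24, flashback_beats_mean=320, flashback_beats_sd=5,
        af_beats_mean=120, af_beats_sd=10, seed=5)
    return af.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return af.extract_features(small_cohort)


@pytest.fixture(scope="session")
def quick_config():
    """Reduced protocol for fast experiment runs on the small cohort."""
    return af.AnalysisConfig(
        n_repetitions=5, sffs_max_size=3, n_selection_repetitions=2,
        test_per_class=(3, 3), seed=0)
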