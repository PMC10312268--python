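import numpy as np
import pytest

from usemkit import synthetic_data as syn
from usemkit.timeseries_io import ROITimeSeries


@pytest.fixture(scope="session")
def small_scenario():
    """Five-node, three-path scenario used by several estimation tests."""
    return syn.make_scenario(dict(
        n_subjects=4, n_endogenous=5, n_exogenous=0, n_timepoints=300,
        n_group_paths=3, n_individual_pool=0, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    return syn.simulate_cohort(small_scenario)


def make_white_noise(T=300, p=4, seed=0, subject_id="wn"):
    rng = np.random.default_rng(seed)
    return ROITimeSeries(
        subject_id=subject_id,
        values=rng.standard_normal((T, p)),
        node_names=[f"n{i + 1}" for i in range(p)])


@pytest.fixture
def white_noise_series():
    return make_white_noise()
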