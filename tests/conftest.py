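import warnings

import pytest

from isofoodweb.baseline import adjust_d15n, site_baselines
from isofoodweb.hier_model import ModelConfig, fit
from isofoodweb.synthetic import default_params, generate


@pytest.fixture(scope="session")
def default_truth():
    return default_params(seed=101)


@pytest.fixture(scope="session")
def dataset(default_truth):
    return generate(default_truth)


@pytest.fixture(scope="session")
def adjusted(dataset):
    """Baseline-corrected consumer table for the session's synthetic draw."""
    return adjust_d15n(dataset.consumer_frame, site_baselines(dataset.baseline))


@pytest.fixture(scope="session")
def d15n_draws(adjusted):
    """One full-default fit of the δ15N model, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(adjusted, ModelConfig(response="d15n_adjusted", seed=7))
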