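import numpy as np
import pytest

from trnameth.age_models import AgeModelSpec, fit_all_windows
from trnameth.synthetic_data import SimulationConfig, simulate_study
from trnameth.window_methylome import map_windows_to_features, quantile_normalize


@pytest.fixture(scope="session")
def default_study():
    """One default-condition synthetic study (planted tRNA hypermethylation)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_study):
    """Blood-cell + batch corrected window fits on the default study."""
    study = default_study
    normed = quantile_normalize(study.matrix)
    results = fit_all_windows(normed, study.samples, AgeModelSpec(model_id=4))
    fmap = map_windows_to_features(study.matrix.windows, study.genes)
    return study, results, fmap


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
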