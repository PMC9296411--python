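import numpy as np
import pytest

from prosodim.cohort import CohortConfig
from prosodim.pipeline import ExperimentConfig, run_experiment
from prosodim.stimuli import default_utterance_pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pair_set():
    """Standard 18 statement-question pairs."""
    return default_utterance_pairs(18, np.random.default_rng(7))


@pytest.fixture(scope="session")
def default_run():
    """One full simulated experiment at the default study scale, shared
    across tests that only inspect its outputs."""
    cfg = ExperimentConfig(cohort=CohortConfig(n_per_cell=10), seed=0,
                           save_plots=False)
    return run_experiment(cfg)
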