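import numpy as np
import pytest

from ezhddm.model import PopulationParams
from ezhddm.wiener import DesignSpec, simulate_hierarchical


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest hierarchical dataset shared by fitting tests."""
    pop = PopulationParams(beta=0.5, criterion="drift")
    design = DesignSpec(n_participants=24, n_trials=40,
                        design_kind="regression", criterion="drift")
    summaries, truth = simulate_hierarchical(
        design, pop, np.random.default_rng(7), dt=1e-3)
    return summaries, truth, pop
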