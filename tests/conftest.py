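import numpy as np
import pytest

from pmdkit.hmm import PMDModel
from pmdkit.simulate import SimulationConfig, simulate_architecture, simulate_track


def filtered_track(arch, sample, min_coverage=5):
    tr = simulate_track(arch, sample)
    return tr[tr["coverage"] >= min_coverage].reset_index(drop=True)


@pytest.fixture(scope="session")
def moderate_sim():
    """Default study conditions: 10-Mb genome, ~50k CpGs, PMD depth 0.6."""
    config = SimulationConfig(seed=1)
    arch = simulate_architecture(config)
    track = filtered_track(arch, "A1")
    model = PMDModel(track, all_positions=arch.positions)
    return config, arch, track, model


@pytest.fixture(scope="session")
def moderate_fit(moderate_sim):
    _, arch, _, model = moderate_sim
    return arch, model, model.fit(dim="auto", seed=0)


@pytest.fixture(scope="session")
def extreme_sim():
    """Extreme methylation loss: same architecture machinery, PMD depth 0.03."""
    config = SimulationConfig(seed=1, extreme_loss=True)
    arch = simulate_architecture(config)
    track = filtered_track(arch, "A1")
    model = PMDModel(track, all_positions=arch.positions)
    return config, arch, track, model


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
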