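import numpy as np
import pytest

from retroprobe import synthetic as syn


@pytest.fixture(scope="session")
def wt_recording():
    """One seeded wild-type insertion recording with ground truth."""
    protocol = syn.InsertionProtocol()
    scenario = syn.RecordingScenario(mode="WT", seed=11)
    return syn.gen_recording(protocol, scenario)


@pytest.fixture(scope="session")
def rd10_recording():
    """A 10 s rd10-mode recording (two 5 s steps) with 3.3/7 Hz oscillations."""
    protocol = syn.InsertionProtocol(n_steps=2)
    scenario = syn.RecordingScenario(mode="rd10", seed=12)
    return syn.gen_recording(protocol, scenario)


@pytest.fixture(scope="session")
def small_stack():
    """One seeded synthetic trauma stack with ground truth."""
    scenario = syn.StackScenario(hole_area_um2=900.0, dead_cell_count=3, seed=21)
    return syn.gen_stack(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
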