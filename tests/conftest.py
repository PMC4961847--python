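import numpy as np
import pytest

import mnpkin as m


@pytest.fixture
def layout():
    return m.default_layout()


@pytest.fixture
def truth():
    return m.KineticTruth(kon_bi=1e7, koff_bi=1e-3)


@pytest.fixture
def batch(layout):
    return m.MNPBatch.from_layout("PD-1", 1e-9, layout)


@pytest.fixture
def truth_map(layout, truth):
    tm = {b: None for b in layout.baits}
    tm["PD-L1"] = truth
    tm["PD-L2"] = truth
    return tm


@pytest.fixture
def noiseless():
    return m.NoiseModel(sigma_rel=0.0, amp_cv=0.0, seed=0)


@pytest.fixture
def clean_dataset(layout, batch, truth_map, noiseless):
    return m.simulate_dataset(layout, batch, truth_map, noiseless, duration=520.0)
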