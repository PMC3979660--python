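import numpy as np
import pytest

import wssmap as w


@pytest.fixture(scope="session")
def demo():
    """Small standard scenario: (hierarchy, populations, truths, config, records)."""
    return w.demo_scenario(1)


@pytest.fixture(scope="session")
def fitted(demo):
    """A quick fit of the improved-water model on the demo scenario,
    shared across tests that only need plausible posterior draws."""
    hierarchy, populations, truths, config, records = demo
    model = w.CoverageModel.from_records(records, hierarchy,
                                         indicator="improved_water")
    return model.fit(n_chains=2, n_iter=1200, n_warmup=600, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
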