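import numpy as np
import pytest

import tacall


@pytest.fixture(scope="session")
def sim_dataset():
    """A modest synthetic dataset shared across model-level tests."""
    cfg = tacall.SimConfig(n_reactions=2000, seed=7)
    traces, labels = tacall.simulate_dataset(cfg)
    ds = tacall.assemble(tacall.normalize_batch(traces), labels)
    return ds


@pytest.fixture(scope="session")
def fitted_model(sim_dataset):
    """A trained two-stage model with its train/test split."""
    train, test = tacall.split(sim_dataset, 0.8, seed=7)
    model = tacall.fit(train, seed=7)
    return model, train, test


def make_trace(reporter, rox, reaction_id="r1", dye="FAM", **kw):
    return tacall.FluorescenceTrace(
        reaction_id=reaction_id, dye=dye,
        reporter=np.asarray(reporter, dtype=float),
        rox=np.asarray(rox, dtype=float), **kw,
    )
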