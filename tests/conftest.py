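import numpy as np
import pytest

import seegfuse as sf

# Small grid keeps the morphology and registration tests fast while leaving
# room for full-length (80 mm) electrodes inside the brain.
TEST_PHANTOM_CFG = dict(
    dims=(96, 104, 96),
    spacing=(2.0, 2.0, 2.0),
    head_semiaxes_mm=(62.0, 76.0, 66.0),
)


@pytest.fixture(scope="session")
def phantom():
    """One shared clean phantom pair (session-scoped: generation costs seconds)."""
    return sf.make_head_phantom(sf.PhantomConfig(**TEST_PHANTOM_CFG, seed=7))


@pytest.fixture(scope="session")
def phantom_with_electrodes(phantom):
    ct, truth, trajectories = sf.insert_electrodes(
        phantom.ct, phantom.brain_mask, sf.ElectrodeSpec(), seed=11
    )
    return phantom, ct, truth, trajectories


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def experiment_report():
    """The masked-vs-unmasked comparison over 10 seeds (shared: minutes of compute)."""
    return sf.run_simulated_experiment(
        seeds=range(10),
        phantom_cfg=sf.PhantomConfig(**TEST_PHANTOM_CFG),
    )
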