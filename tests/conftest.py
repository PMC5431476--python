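import numpy as np
import pytest

from retmodal.phantom import PhantomConfig, generate_case

REDUCED_DIMS = (128, 32, 256)


@pytest.fixture(scope="session")
def small_case():
    """One reduced-dims phantom eye shared by read-only tests."""
    cfg = PhantomConfig(grid_dims=REDUCED_DIMS, n_foci=5, n_exudates=2, rng_seed=11)
    return generate_case(cfg, eye_id="fixture_eye", label="NPDR")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
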