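import logging

import numpy as np
import pytest

# clamp/ordering warnings are exercised deliberately; keep test output quiet
logging.getLogger("dogblur").setLevel(logging.ERROR)

from dogblur import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def brain_phantom() -> np.ndarray:
    """One deterministic 128x128 brain-like phantom."""
    return generate_phantom(PhantomSpec(seed=7, n_regions=4, layout="brain"))


@pytest.fixture(scope="session")
def cardiac_phantom() -> np.ndarray:
    return generate_phantom(PhantomSpec(seed=11, n_regions=4, layout="cardiac"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
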