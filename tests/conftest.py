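import numpy as np
import pytest

from quadturn.body_mechanics import BodyParams


@pytest.fixture(scope="session")
def params() -> BodyParams:
    """Mouse-scale body constants used throughout the suite."""
    return BodyParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
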