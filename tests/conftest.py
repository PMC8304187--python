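import numpy as np
import pytest

from petscore import PhantomSpec, SUVVolume, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom shared across tests (read-only)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture
def make_volume():
    def _make(data, spacing=(1.0, 1.0, 1.0)):
        return SUVVolume(data=np.asarray(data, dtype=float), spacing=spacing)

    return _make


def ball_mask(shape, center, radius):
    grids = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
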