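import numpy as np
import pytest

from gastronir.simulate import SyntheticConfig
from gastronir.spectra import SpectrumSet, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spectra(rng):
    grid = WavelengthGrid(400.0, 2.0, 60)
    X = rng.normal(0.5, 0.1, (8, 60))
    labels = ["A", "A", "B", "B", "C", "C", "A", "B"]
    return SpectrumSet(
        grid=grid,
        absorbance=X,
        sample_ids=[f"s{i}" for i in range(8)],
        origin_labels=labels,
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Down-scaled synthetic config for fast pipeline-level tests."""
    return SyntheticConfig().scaled(0.25)
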