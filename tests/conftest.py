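import numpy as np
import pytest

from glucospec import SpectrumSet, SyntheticConfig, WavelengthGrid, generate_dataset


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size synthetic dataset under the study-condition defaults."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture()
def small_spectra(grid) -> SpectrumSet:
    rng = np.random.default_rng(7)
    n = 6
    matrix = 0.4 + 0.05 * rng.standard_normal((n, grid.size))
    return SpectrumSet(grid, [f"S{i}" for i in range(n)], matrix)
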