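import numpy as np
import pytest

from aggsim import (
    CellArrangement,
    GeneratorConfig,
    VulnerabilityField,
    generate_arrangement,
)


@pytest.fixture(scope="session")
def full_scale_arrangement():
    """The full-scale banded arrangement: 10 002 cells, 27.3 µm mean NND,
    middle-third band at 0.8x spacing, periodic boundaries."""
    return generate_arrangement(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def reduced_arrangement():
    """A reduced (3 000 cell) banded arrangement for simulation-heavy tests."""
    return generate_arrangement(GeneratorConfig(n_cells=3000, seed=2))


@pytest.fixture()
def small_arrangement():
    """A 40-cell periodic box, tractable for brute-force oracles."""
    rng = np.random.default_rng(7)
    return CellArrangement(rng.uniform(0, 500, (40, 2)), 500, 500, "periodic")


@pytest.fixture()
def full_vulnerability():
    def make(arrangement):
        return VulnerabilityField.constant(arrangement.n_cells)

    return make
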