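import numpy as np
import pytest

from rangeshape import (
    ClimateLayers,
    DomainMask,
    ElevationBands,
    GridSpec,
    LandscapeSpec,
    make_landscape,
    make_species_pool,
)


@pytest.fixture(scope="session")
def grid6x18() -> GridSpec:
    return GridSpec(6, 18, 3)


@pytest.fixture
def line_domain() -> DomainMask:
    """A 1x3 all-suitable strip: cells A=(0,0), B=(0,1), C=(0,2)."""
    cells = {(0, 0), (0, 1), (0, 2)}
    return DomainMask("line", cells, cells)


@pytest.fixture(scope="session")
def ridge_landscape():
    return make_landscape(LandscapeSpec(kind="ridge", seed=1))


@pytest.fixture(scope="session")
def ridge_species(ridge_landscape):
    return make_species_pool(ridge_landscape, n_species=20, seed=2)


@pytest.fixture
def stepped_elevation():
    """One coarse cell of 16 fine cells banded 0-3000 m in 200 m steps."""
    centers = np.arange(16, dtype=float).reshape(4, 4) * 200.0
    return ElevationBands(centers, centers + 200.0)


@pytest.fixture
def flat_climate():
    shape = (4, 4)
    return ClimateLayers(
        np.full(shape, 20.0), np.full(shape, 1000.0),
        np.full(shape, 300.0), np.full(shape, 40.0),
    )
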