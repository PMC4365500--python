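import numpy as np
import pytest

from vaultmorph import (
    DifferentiationParams,
    GrowthParams,
    TuringParams,
    build_interval_mesh,
    build_sheet_mesh,
)


@pytest.fixture
def turing_defaults() -> TuringParams:
    return TuringParams()


@pytest.fixture
def diff_defaults() -> DifferentiationParams:
    return DifferentiationParams()


@pytest.fixture
def growth_defaults() -> GrowthParams:
    return GrowthParams()


@pytest.fixture
def unit_sheet():
    return build_sheet_mesh(1.0, 1.0, 0.1)


@pytest.fixture
def periodic_interval():
    return build_interval_mesh(10.0, 200, periodic=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150319)
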