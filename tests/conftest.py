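import numpy as np
import pytest

from lnpsaxs import (
    NoiseModel,
    default_q_grid,
    generate_curve,
    preset,
    sweep_base,
)


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture
def base_params():
    """Base simulation geometry: R0=25 nm, three shells, 0.01-scale SLDs."""
    return sweep_base()


@pytest.fixture
def mrna_params():
    """mRNA-LNP truth row including the quasi-Bragg peak at 1.27 nm^-1."""
    return preset("table1-mrna")


@pytest.fixture
def empty_params():
    """Empty-LNP truth row (no peak)."""
    return preset("table1-empty")


@pytest.fixture
def noisy_empty_curve(empty_params):
    return generate_curve(empty_params, noise=NoiseModel(level=0.01, seed=7))
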