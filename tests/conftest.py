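import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `helpers`

from ancestrypaint.model import AncestryCodebook
from ancestrypaint.synth import SimulationConfig, write_fixture


@pytest.fixture
def codebook3():
    return AncestryCodebook.from_names(("MiddleEast", "Europe", "Africa"))


@pytest.fixture(scope="session")
def small_config():
    """Small but multi-chromosome config: fast and structurally realistic."""
    return replace(
        SimulationConfig(),
        genome=tuple((str(i), 8_000_000) for i in range(1, 4)),
        n_samples=4,
        window_bp=400_000,
        mean_tract_bp=2_000_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(small_config, out)


@pytest.fixture(scope="session")
def genome22_config():
    """22-chromosome config at reduced length for karyogram tests."""
    return replace(
        SimulationConfig(),
        genome=tuple((str(i), 10_000_000) for i in range(1, 23)),
        n_samples=2,
        window_bp=500_000,
        mean_tract_bp=2_500_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def genome22_fixture(genome22_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture22")
    return write_fixture(genome22_config, out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
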