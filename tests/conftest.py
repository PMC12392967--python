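import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from ampedit import EditSpec, build_reference_panel, default_guides


@pytest.fixture(scope="session")
def panel():
    """Small synthetic gene-family panel shared across tests."""
    return build_reference_panel(seed=3)


@pytest.fixture(scope="session")
def guides():
    return default_guides()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def null_spec():
    return EditSpec.null()


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
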