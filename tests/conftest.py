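import json
from pathlib import Path

import numpy as np
import pytest

from scrubmatch.cli_io import read_cohort
from scrubmatch.profiles import CompatibilityMatrix

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def cohort_a():
    """The 3x3 hand-scored fixture cohort: (patients, providers)."""
    return read_cohort(FIXTURES / "cohort_a.json")


@pytest.fixture(scope="session")
def cohort_a_path():
    return FIXTURES / "cohort_a.json"


def random_matrix(rng: np.random.Generator, n: int, m: int) -> CompatibilityMatrix:
    """Random score matrix with almost-surely distinct entries."""
    return CompatibilityMatrix(
        patients=tuple(f"p{k}" for k in range(n)),
        providers=tuple(f"r{k}" for k in range(m)),
        scores=rng.uniform(0.0, 1.0, size=(n, m)),
    )
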