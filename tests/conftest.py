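import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from lncid.fixtures import FixtureSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60+60 folded synthetic transcripts for unit-level table building."""
    spec = FixtureSpec(n_mrna=60, n_lncrna=60, length_range=(200, 400), seed=42)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def medium_dataset():
    """500+500 folded synthetic transcripts for distributional checks."""
    spec = FixtureSpec(n_mrna=500, n_lncrna=500, seed=7)
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
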