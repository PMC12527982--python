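import numpy as np
import pytest
from hypothesis import settings

from sosdep import default_matrix
from sosdep.synthetic_fixtures import default_spec, generate_fixture

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def fixture_bundle():
    """One fully generated synthetic genome shared across the session."""
    spec = default_spec(42)
    genome, regions, truth, _ = generate_fixture(spec)
    return spec, genome, regions, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_window(rng, matrix, n=1):
    """Random core-preserving 20-mers (valid scan candidates)."""
    core = dict(matrix.core_positions)
    out = []
    for _ in range(n):
        chars = [
            core.get(i, "ACGT"[rng.integers(4)])
            for i in range(matrix.motif_length)
        ]
        out.append("".join(chars))
    return out if n > 1 else out[0]
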