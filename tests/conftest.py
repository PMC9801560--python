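import numpy as np
import pytest

from pbdtss.pbd import PBDParameters, QuadratureGrid


@pytest.fixture(scope="session")
def params():
    return PBDParameters()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse quadrature for oracle comparisons (identical sums either route)."""
    return QuadratureGrid(n_points=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260331)


def random_dna(rng, length, n=None):
    bases = np.array(list("ACGT"))
    if n is None:
        return "".join(rng.choice(bases, size=length))
    return ["".join(rng.choice(bases, size=length)) for _ in range(n)]
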