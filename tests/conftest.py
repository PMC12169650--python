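import numpy as np
import pytest

from dnaadapt.rigidbase import Frame
from dnaadapt.synthetic import (APT_SEQUENCE, DoubleWellPotential,
                                build_duplex, generate_hills)


def random_frame(rng) -> Frame:
    """Uniformly random proper rotation + offset, for invariance checks."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return Frame(R, rng.normal(scale=10.0, size=3))


@pytest.fixture(scope="session")
def bform_duplex():
    return build_duplex(APT_SEQUENCE)


@pytest.fixture(scope="session")
def doublewell_hills():
    """A converged biased run over the synthetic double well (25/45 deg)."""
    return generate_hills(DoubleWellPotential(minima=(25.0, 45.0), barrier=5.0),
                          duration_ns=52.0, seed=3)
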