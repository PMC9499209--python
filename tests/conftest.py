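import numpy as np
import pytest

from atacbind.fragments import FragmentRecord
from atacbind.motifs import PWM
from atacbind.simulate import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_pwm():
    # 4-mer, strongly skewed, non-degenerate
    mat = np.array(
        [
            [8.0, 1.0, 2.0, 1.0],
            [1.0, 7.0, 1.0, 1.0],
            [0.5, 1.0, 6.0, 1.0],
            [0.5, 1.0, 1.0, 7.0],
        ]
    )
    return PWM("toy4", mat)


@pytest.fixture
def planted_fragments():
    """50 fragments with hand-known cut positions on one chromosome."""
    rng = np.random.default_rng(7)
    frags = []
    for _ in range(50):
        start = int(rng.integers(100, 900))
        size = int(rng.integers(30, 300))
        frags.append(FragmentRecord("chr1", start, start + size))
    return frags


@pytest.fixture(scope="session")
def small_sim():
    """Small but realistic fixture shared by read-only tests."""
    return simulate(
        SimConfig(
            genome_len=60_000,
            n_bound_sites=30,
            n_unbound_sites=30,
            background_cut_rate=0.5,
            footprint_depth=0.1,
            seed=42,
        )
    )
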