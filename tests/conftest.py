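import numpy as np
import pytest

from mmlsub import GeneratorSpec, generate_benchmark, random_reversible_base


@pytest.fixture(scope="session")
def base_matrix():
    """A seeded random reversible base matrix at ~1% expected change."""
    return random_reversible_base(np.random.default_rng(123))


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40-pair synthetic benchmark with its truth table, matrix and background."""
    spec = GeneratorSpec(n_pairs=40, seed=7)
    bench, truth, M, P = generate_benchmark(spec)
    return bench, truth, M, P
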