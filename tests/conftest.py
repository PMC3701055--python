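import numpy as np
import pytest

from grninfer import SyntheticSpec, make_dataset
from grninfer.benchmark import run_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-gene / 8-TF / 100-sample known-truth instance for fast tests."""
    return make_dataset(SyntheticSpec(n_genes=20, n_tfs=8, n_samples=100, seed=7))


@pytest.fixture(scope="session")
def benchmark_result():
    """The standard 10-seed end-to-end benchmark (50 genes, 20 TFs,
    200 samples) shared by all whole-pipeline assertions."""
    return run_benchmark(n_seeds=10, base_seed=0)
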