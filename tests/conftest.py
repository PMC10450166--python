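import numpy as np
import pytest

from plasmeld.metrics import confusion, prf1
from plasmeld.synthetic import SyntheticSpec, generate_benchmark
from plasmeld.workflow import fit_pooled_pipeline


@pytest.fixture(scope="session")
def benchmark():
    """Mid-size synthetic benchmark shared by pipeline-level tests."""
    return generate_benchmark(
        SyntheticSpec(seed=7, n_orders=3, plasmids_per_order=8, chromosomes_per_order=5)
    )


@pytest.fixture(scope="session")
def fitted(benchmark):
    """Pooled PC pipeline trained on the shared benchmark (seed-fixed)."""
    return fit_pooled_pipeline(benchmark, seed=0)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small, fast benchmark for tests that only need structure."""
    return generate_benchmark(
        SyntheticSpec(seed=3, n_orders=2, plasmids_per_order=4, chromosomes_per_order=3)
    )


def evaluate_f1(predictions, labeled):
    truth = [bool(label) for _, label, _ in labeled]
    predicted = [p.label == "plasmid" for p in predictions]
    return prf1(confusion(predicted, truth))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
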