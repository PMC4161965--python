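import numpy as np
import pytest

from countgsa import CountMatrix, GeneSetCollection, PhenotypeLabels


@pytest.fixture
def small_counts():
    """12 genes x 8 samples of Poisson-ish counts, deterministic."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(12)]
    samples = [f"s{i}" for i in range(8)]
    return CountMatrix(genes, samples, rng.poisson(40, size=(12, 8)))


@pytest.fixture
def small_labels():
    samples = [f"s{i}" for i in range(8)]
    classes = ["A", "A", "A", "A", "B", "B", "B", "B"]
    return PhenotypeLabels(samples, classes, ("A", "B"))


@pytest.fixture
def small_sets():
    return GeneSetCollection.from_dict(
        {
            "even": [f"G{i}" for i in range(0, 12, 2)],
            "odd": [f"G{i}" for i in range(1, 12, 2)],
            "first": [f"G{i}" for i in range(5)],
        }
    )
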