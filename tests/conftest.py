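import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from modelcongruence.data_io import ExpressionMatrix, SampleAnnotation
from modelcongruence.synthetic import make_worked_fixture


@pytest.fixture(scope="session")
def worked():
    return make_worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def two_class_matrix(n_per_class=20, n_genes=10, sep=3.0, noise=0.1, seed=0,
                     target="A", other="B"):
    """Tiny separable two-class tumor matrix: classes at +/- sep on gene 0."""
    rng = np.random.default_rng(seed)
    vals = noise * rng.standard_normal((n_genes, 2 * n_per_class))
    vals[0, :n_per_class] += sep
    vals[0, n_per_class:] -= sep
    ids = [f"s{i}" for i in range(2 * n_per_class)]
    x = ExpressionMatrix(gene_ids=[f"g{i}" for i in range(n_genes)],
                         sample_ids=ids, values=vals)
    ann = [SampleAnnotation(sample_id=s, source="tumor",
                            class_label=target if i < n_per_class else other)
           for i, s in enumerate(ids)]
    return x, ann


@pytest.fixture()
def separable():
    return two_class_matrix()
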