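import numpy as np
import pytest

from paretosig.data_io import ExpressionMatrix, GroupLabels


def make_matrix(values, gene_ids=None, sample_ids=None, value_scale="other"):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    return ExpressionMatrix(gene_ids, sample_ids, values, value_scale)


def make_groups(sample_ids, n_control):
    return GroupLabels(
        {s: ("control" if i < n_control else "case") for i, s in enumerate(sample_ids)}
    )


@pytest.fixture
def tiny_matrix():
    return make_matrix(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        gene_ids=["TP63", "KRT6A", "IVL"],
        sample_ids=["sA", "sB"],
        value_scale="counts",
    )


@pytest.fixture
def two_blobs():
    """40 points in two well-separated Gaussian blobs; labels 0/1."""
    rng = np.random.default_rng(42)
    a = rng.normal(-10.0, 0.5, size=(20, 2))
    b = rng.normal(10.0, 0.5, size=(20, 2))
    X = np.vstack([a, b])
    labels = np.array([0] * 20 + [1] * 20)
    return X, labels
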