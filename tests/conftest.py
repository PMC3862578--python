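import numpy as np
import pytest

from wrapsel import LabeledDataset, SyntheticSpec, generate_two_class_dataset


def make_dataset(matrix, labels, gene_prefix="g", sample_prefix="s"):
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    return LabeledDataset(
        matrix=matrix,
        gene_ids=tuple(f"{gene_prefix}{j}" for j in range(d)),
        sample_ids=tuple(f"{sample_prefix}{i}" for i in range(n)),
        labels=None if labels is None else np.asarray(labels, dtype=np.int8),
    )


@pytest.fixture
def toy_1d():
    """1-D two-class toy: NEGATIVE at {0, 2}, POSITIVE at {4, 6}."""
    return make_dataset([[0.0], [2.0], [4.0], [6.0]], [0, 0, 1, 1])


@pytest.fixture
def planted_dataset():
    """One overwhelming planted gene (delta=10) among 50 noise genes."""
    spec = SyntheticSpec(
        n_pos=8, n_neg=8, n_genes=51, planted=((0, 10.0),), seed=7
    )
    return spec, generate_two_class_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
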