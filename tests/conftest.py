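import numpy as np
import pytest

from reosig.io import ExpressionMatrix
from reosig.pairs import GT, LT, ReversalSignature


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int,
                  tie_prob: float = 0.0) -> ExpressionMatrix:
    """Random expression matrix; with tie_prob > 0 values are coarsely rounded
    so within-sample ties actually occur."""
    gene_ids = np.sort(rng.choice(np.arange(1, 20 * n_genes), size=n_genes, replace=False))
    values = rng.normal(size=(n_genes, n_samples)) * 2.0
    if tie_prob > 0 and rng.random() < tie_prob:
        values = np.round(values * 2) / 2
    return ExpressionMatrix(gene_ids, tuple(f"s{j}" for j in range(n_samples)), values)


@pytest.fixture
def four_pair_signature() -> ReversalSignature:
    """Signature over genes 1..8: (1,2,gt) (3,4,lt) (5,6,gt) (7,8,lt)."""
    return ReversalSignature(
        np.array([1, 3, 5, 7]), np.array([2, 4, 6, 8]),
        np.array([GT, LT, GT, LT], dtype=np.int8),
        mature_label="adult", immature_label="esc",
    )
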