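import numpy as np
import pytest

from padog.io import ExpressionDataset, GeneSetCollection


def make_dataset(matrix, group=None, block=None, control="control"):
    matrix = np.asarray(matrix, dtype=float)
    g, s = matrix.shape
    if group is None:
        group = np.array(["control"] * (s // 2) + ["case"] * (s - s // 2))
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(s)],
        group=np.asarray(group),
        control_level=control,
        block=None if block is None else np.asarray(block),
    )


@pytest.fixture
def toy_dataset():
    """9 genes x 6 samples (3 vs 3), fixed seed, mild shift in genes 0-2."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((9, 6))
    X[:3, 3:] += 1.5
    return make_dataset(X)


@pytest.fixture
def toy_collection():
    return GeneSetCollection({
        "S1": ["g0", "g1", "g2"],
        "S2": ["g3", "g4", "g5"],
        "S3": ["g6", "g7", "g8"],
    })
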