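import numpy as np
import pandas as pd
import pytest

from markersig import OmicsDataset, SampleSelection


@pytest.fixture
def small_dataset():
    """12 samples x 6 features, two annotated cell types, one 2D embedding."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(12, 6))
    X[:6, 0] += 5.0  # feature f0 is a marker for the B group
    sample_ids = [f"s{i}" for i in range(12)]
    return OmicsDataset(
        matrix=X,
        feature_names=[f"f{j}" for j in range(6)],
        sample_ids=sample_ids,
        annotations=pd.DataFrame(
            {"cell_type": ["B"] * 6 + ["T"] * 6}, index=sample_ids
        ),
        embeddings={"X_pca": rng.normal(size=(12, 2))},
    )


@pytest.fixture
def selection_pair(small_dataset):
    a = SampleSelection(np.arange(12) < 6, provenance="label:cell_type=B")
    b = SampleSelection(np.arange(12) >= 6, provenance="label:cell_type=T")
    return a, b


def make_dataset(X, annotations=None, embedding=None, seed=0):
    """Wrap a raw matrix into an OmicsDataset with default bookkeeping."""
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    ids = [f"s{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    return OmicsDataset(
        matrix=X,
        feature_names=[f"f{j}" for j in range(f)],
        sample_ids=ids,
        annotations=pd.DataFrame(annotations or {}, index=ids),
        embeddings={"emb": embedding if embedding is not None else rng.normal(size=(n, 2))},
    )
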