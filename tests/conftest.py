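from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexnet.io import DatasetCollection, ExpressionDataset


def make_dataset(
    dataset_id: str,
    values: dict[str, list[float]],
    groups: list[str] | None = None,
    tissue: str = "mixed",
) -> ExpressionDataset:
    """Small hand-written dataset: values maps gene -> per-sample expression."""
    frame = pd.DataFrame(values).T
    n = frame.shape[1]
    samples = [f"{dataset_id}_s{i}" for i in range(n)]
    frame.columns = samples
    frame.index.name = "gene_id"
    if groups is None:
        groups = ["g1"] * (n // 2) + ["g2"] * (n - n // 2)
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=frame.astype(float),
        replicate_group=pd.Series(groups, index=samples),
        tissue=tissue,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160811)


@pytest.fixture
def toy_collection() -> DatasetCollection:
    """Two tiny datasets over a shared 4-gene universe, one per tissue."""
    rng = np.random.default_rng(42)
    def noisy(n=6):
        return list(rng.normal(8.0, 1.0, n))
    d1 = make_dataset(
        "dsA",
        {"gx": noisy(), "g1": noisy(), "g2": noisy(), "g3": noisy()},
        tissue="root",
    )
    d2 = make_dataset(
        "dsB",
        {"gx": noisy(), "g1": noisy(), "g2": noisy(), "g3": noisy()},
        tissue="leaf",
    )
    return DatasetCollection([d1, d2])
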