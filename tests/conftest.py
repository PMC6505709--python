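import numpy as np
import pandas as pd
import pytest

from adascreen import StagedExpressionMatrix, SyntheticDesign, generate
from adascreen.matrix import STAGES


def build_matrix(arr, samples_per_stage, gene_ids=None):
    """StagedExpressionMatrix from an array and four per-stage counts."""
    arr = np.asarray(arr, dtype=float)
    n_genes = arr.shape[0]
    gene_ids = gene_ids or [f"g{k}" for k in range(1, n_genes + 1)]
    sample_ids, stage_of = [], {}
    k = 0
    for stage, count in zip(STAGES, samples_per_stage):
        for _ in range(count):
            k += 1
            sid = f"s{k}"
            sample_ids.append(sid)
            stage_of[sid] = stage
    values = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    return StagedExpressionMatrix.from_dataframe(values, stage_of)


def random_matrix(rng, n_genes, samples_per_stage=(2, 2, 2, 2)):
    n_samples = sum(samples_per_stage)
    arr = rng.normal(8.0, 1.5, size=(n_genes, n_samples))
    return build_matrix(arr, samples_per_stage)


@pytest.fixture
def toy_control_block():
    """3 genes x 2 samples, both control: the hand-computable example."""
    values = pd.DataFrame(
        [[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return StagedExpressionMatrix.from_dataframe(
        values, {"s1": "control", "s2": "control"}
    )


@pytest.fixture
def small_four_stage():
    """6 genes, 2 samples per stage, fixed random values."""
    rng = np.random.default_rng(7)
    return random_matrix(rng, 6)


@pytest.fixture(scope="session")
def seeded_synthetic():
    """The packaged 1,000-gene synthetic study (seed 42) with truth."""
    return generate(SyntheticDesign(seed=42))
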