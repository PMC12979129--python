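import numpy as np
import pandas as pd
import pytest

from zincsig.datasets_io import ExpressionDataset


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, log2-scale intensity values."""
    return pd.DataFrame(
        [[5.0, 6.0, 7.0, 8.0],
         [9.0, 9.5, 10.0, 10.5],
         [4.0, 4.2, 4.4, 4.6]],
        index=["MT1F", "MT1G", "SLC30A1"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def two_group_labels():
    return pd.Series(["treated", "treated", "control", "control"],
                     index=["s1", "s2", "s3", "s4"])


@pytest.fixture
def gaussian_dataset():
    """200-gene intensity dataset, 4 vs 4, already on log2 scale."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(200)]
    samples = [f"s{j}" for j in range(8)]
    mu = rng.uniform(4, 12, 200)
    sig = rng.uniform(0.2, 0.6, 200)
    vals = rng.normal(mu[:, None], sig[:, None], (200, 8))
    values = pd.DataFrame(vals, index=genes, columns=samples)
    groups = pd.Series(["treated"] * 4 + ["control"] * 4, index=samples)
    return ExpressionDataset(dataset_id="GAUSS", platform="intensity",
                             values=values, groups=groups, log_scale=True)


def write_tsv_matrix(path, frame):
    out = frame.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_tsv_metadata(path, samples, groups, **extra_cols):
    meta = pd.DataFrame({"sample": samples, "group": groups})
    for name, vals in extra_cols.items():
        meta[name] = vals
    meta.to_csv(path, sep="\t", index=False)
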