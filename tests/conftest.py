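import numpy as np
import pandas as pd
import pytest

from devtraj.io import CountMatrix, SampleTable


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 genes x 4 samples with hand-checkable numbers."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 90],
            "s2": [5, 3, 992],
            "s3": [0, 0, 50],
            "s4": [7, 2, 41],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    lengths = pd.Series([1000, 500, 2000], index=counts.index)
    return CountMatrix(counts, lengths)


@pytest.fixture
def two_group_table() -> SampleTable:
    """Minimal 2 time points x 2 replicates design."""
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "condition": "c",
                "time_h": [0, 0, 1, 1],
                "replicate": ["r1", "r2", "r1", "r2"],
            }
        )
    )


def nb_counts(rng, mu, phi, size):
    """Reference NB sampler (mean/dispersion parameterization)."""
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def make_count_matrix(values, gene_length=1000) -> CountMatrix:
    """Wrap an array (genes x samples) into a CountMatrix with unit lengths."""
    values = np.asarray(values)
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return CountMatrix(df, pd.Series(gene_length, index=df.index))


def make_samples(times, condition="c", n_reps=1, sample_ids=None) -> SampleTable:
    """Sample table from a list of times (replicated n_reps times each)."""
    rows = []
    for t in times:
        for r in range(1, n_reps + 1):
            rows.append((f"{condition}_{t:g}_r{r}", condition, float(t), f"r{r}"))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "time_h", "replicate"])
    if sample_ids is not None:
        df["sample_id"] = sample_ids
    return SampleTable(df)
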