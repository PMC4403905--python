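"""RPKM standardization, low-expression filtering and profile scaling.

RPKM (reads per kilobase of transcript per million mapped reads) for gene g
in sample s:

    rpkm(g, s) = count(g, s) / (length_kb(g) * total_reads_millions(s))

The per-sample total is the column sum of the supplied counts — downstream
of read counting that is the only depth measure available, and any
difference from the original run-level mapped total is a per-sample
constant.

Filtering retains genes with >= ``threshold`` reads in at least one sample
of an experiment (default 30); the canonical pipeline order is
filter-per-experiment first, then intersect the surviving gene sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "rpkm",
    "filter_low_expression",
    "intersect_genes",
    "standardize_profiles",
]

logger = logging.getLogger(__name__)


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, genes x samples.

    Raises ``ValueError`` naming any sample whose total read count is zero.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total reads: {zero}")
    length_kb = counts.gene_lengths_bp.to_numpy() / 1000.0
    denom = np.outer(length_kb, totals.to_numpy() / 1e6)
    return pd.DataFrame(
        counts.counts.to_numpy() / denom,
        index=counts.gene_ids,
        columns=counts.sample_ids,
    )


def filter_low_expression(counts: CountMatrix, threshold: int = 30) -> CountMatrix:
    """Drop genes whose count is below ``threshold`` in every sample.

    A gene survives iff max over samples of its count is >= threshold; gene
    order is preserved.  Idempotent, and monotone in the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (counts.counts >= threshold).any(axis=1)
    return CountMatrix(counts.counts.loc[keep], counts.gene_lengths_bp)


def intersect_genes(a, b):
    """Restrict two matrices to their shared genes, in a common order.

    Accepts :class:`CountMatrix` or expression DataFrames (genes x samples)
    in either slot; returns the pair restricted to the intersection in the
    gene order of ``a``.  Raises on an empty intersection.
    """
    genes_a = a.gene_ids if isinstance(a, CountMatrix) else a.index
    genes_b = b.gene_ids if isinstance(b, CountMatrix) else b.index
    shared = genes_a[genes_a.isin(set(genes_b))]
    if len(shared) == 0:
        raise ValueError("gene sets are disjoint: empty intersection")

    def _take(x):
        if isinstance(x, CountMatrix):
            return x.subset_genes(shared)
        return x.loc[shared]

    return _take(a), _take(b)


def standardize_profiles(expr: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Per-gene standardization of an expression matrix.

    mode='none'   identity (default — preserves cross-gene amplitudes);
    mode='zscore' per-gene (x - mean) / sd over samples, with zero-variance
                  genes mapped to all-zeros (flagged in the log);
    mode='max'    per-gene division by the row maximum, constant-zero genes
                  staying zero.

    Only per-gene transformations; sample order is untouched.
    """
    if mode == "none":
        return expr.copy()
    vals = expr.to_numpy(dtype=float)
    if mode == "zscore":
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        flat = sd[:, 0] == 0
        if flat.any():
            logger.warning(
                "%d zero-variance genes set to all-zero z-scores", int(flat.sum())
            )
        sd[flat] = 1.0
        out = (vals - mu) / sd
        out[flat.nonzero()[0], :] = 0.0
    elif mode == "max":
        mx = vals.max(axis=1, keepdims=True)
        zero = mx[:, 0] == 0
        mx[zero] = 1.0
        out = vals / mx
    else:
        raise ValueError(f"unknown mode {mode!r}; use none, zscore or max")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
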