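"""Tabular input/output and validation of the joint data model.

All on-disk formats are plain TSV with a header row:

* ``counts.tsv`` — genes x samples; first column is the gene identifier,
  remaining column names are sample identifiers, cells are integer read
  counts.
* ``gene_lengths.tsv`` — two columns ``gene_id``, ``length_bp``.
* ``samples.tsv`` — four columns ``sample_id``, ``condition``, ``time_h``,
  ``replicate``.
* ``annotations.tsv`` — two columns ``gene_id``, ``term_id`` (one row per
  gene/term pairing).

Gene and sample identifiers are opaque strings.  Time is a real number of
hours, never an index, so irregular sampling (hourly then two-hourly) is
first-class.  A missing sample is represented by the absence of its row in
``samples.tsv`` (and of its column in ``counts.tsv``), never by NA cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "AnnotationMap",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts (genes x samples) with per-gene transcript lengths.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = gene ids (unique),
        columns = sample ids (unique).
    gene_lengths_bp
        Series of positive integer mapable transcript lengths, indexed by
        gene id; must cover every gene in ``counts``.
    """

    counts: pd.DataFrame
    gene_lengths_bp: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if c.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = _first_offender(c, lambda v: v != np.round(v))
                raise ValueError(f"non-integer count at {bad}")
            object.__setattr__(self, "counts", c.astype(np.int64))
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = _first_offender(self.counts, lambda v: v < 0)
            raise ValueError(f"negative count at {bad}")
        lengths = self.gene_lengths_bp
        missing = c.index.difference(lengths.index)
        if len(missing):
            raise ValueError(
                f"genes missing from length table: {missing[:5].tolist()}"
            )
        lengths = lengths.reindex(c.index)
        if (lengths <= 0).any() or lengths.isna().any():
            bad = lengths.index[(lengths <= 0) | lengths.isna()][:5].tolist()
            raise ValueError(f"non-positive gene length for: {bad}")
        object.__setattr__(self, "gene_lengths_bp", lengths.astype(np.int64))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, gene_ids) -> "CountMatrix":
        """Restrict to ``gene_ids`` (order as given)."""
        return CountMatrix(self.counts.loc[list(gene_ids)], self.gene_lengths_bp)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.gene_lengths_bp)


def _first_offender(df: pd.DataFrame, pred) -> str:
    mask = pred(df.to_numpy())
    i, j = np.argwhere(mask)[0]
    return f"gene {df.index[i]!r}, sample {df.columns[j]!r}"


SAMPLE_COLUMNS = ["sample_id", "condition", "time_h", "replicate"]


@dataclass(frozen=True)
class SampleTable:
    """Per-sample condition, time in hours and replicate label.

    Rows are kept in the canonical order (condition, time_h, replicate) so
    that validation is independent of input row order.  The (condition,
    time_h, replicate) triple must be unique and every condition must have
    at least two distinct time points.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df = df[SAMPLE_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["replicate"] = df["replicate"].astype(str)
        df["time_h"] = pd.to_numeric(df["time_h"])
        if (df["time_h"] < 0).any():
            bad = df.loc[df["time_h"] < 0, "sample_id"].tolist()
            raise ValueError(f"negative time_h for samples: {bad[:5]}")
        if df["sample_id"].duplicated().any():
            bad = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {bad[:5]}")
        trip = df[["condition", "time_h", "replicate"]]
        if trip.duplicated().any():
            bad = trip[trip.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (condition, time_h, replicate): {bad}")
        for cond, sub in df.groupby("condition"):
            if sub["time_h"].nunique() < 2:
                raise ValueError(
                    f"condition {cond!r} has fewer than 2 distinct time points"
                )
        df = df.sort_values(["condition", "time_h", "replicate"], kind="mergesort")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    def for_condition(self, condition: str) -> pd.DataFrame:
        sub = self.df[self.df["condition"] == condition]
        if sub.empty:
            raise KeyError(f"no samples for condition {condition!r}")
        return sub.reset_index(drop=True)

    def times(self, condition: str) -> np.ndarray:
        """Sorted distinct time points of one condition."""
        return np.sort(self.for_condition(condition)["time_h"].unique())

    def samples_at(self, condition: str, time_h: float) -> list[str]:
        sub = self.for_condition(condition)
        return sub.loc[sub["time_h"] == time_h, "sample_id"].tolist()


@dataclass(frozen=True)
class AnnotationMap:
    """Many-to-many gene -> annotation-term map (flat, GO-style).

    Un-annotated genes are simply absent; every term must annotate at least
    one gene.
    """

    gene_to_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationMap":
        mapping: dict[str, set[str]] = {}
        for gene, term in pairs:
            mapping.setdefault(str(gene), set()).add(str(term))
        return cls({g: frozenset(t) for g, t in mapping.items()})

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}

    def restricted_to(self, genes) -> "AnnotationMap":
        """Drop genes outside ``genes`` (and thereby empty terms)."""
        keep = set(map(str, genes))
        return AnnotationMap(
            {g: ts for g, ts in self.gene_to_terms.items() if g in keep}
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, lengths_path) -> CountMatrix:
    """Read a counts TSV plus a gene-length TSV into a validated CountMatrix.

    Raises ``ValueError`` naming the offending cell for negative or
    non-integer counts, duplicate gene ids, or genes without a length.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    lengths = pd.read_csv(lengths_path, sep="\t")
    if lengths.shape[1] < 2:
        raise ValueError("gene length table needs columns gene_id, length_bp")
    lengths = lengths.set_index(lengths.columns[0]).iloc[:, 0]
    lengths.index = lengths.index.astype(str)
    if lengths.index.has_duplicates:
        bad = lengths.index[lengths.index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate gene ids in length table: {bad}")
    return CountMatrix(counts, lengths)


def write_counts(cm: CountMatrix, path, lengths_path=None) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if lengths_path is not None:
        lg = cm.gene_lengths_bp.rename("length_bp")
        lg.index.name = "gene_id"
        lg.to_csv(lengths_path, sep="\t")


def read_samples(path) -> SampleTable:
    """Read and validate a samples.tsv (sample_id, condition, time_h, replicate)."""
    return SampleTable(pd.read_csv(path, sep="\t"))


def write_samples(st: SampleTable, path) -> None:
    st.df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("annotation table needs columns gene_id, term_id")
    return AnnotationMap.from_pairs(df.iloc[:, :2].itertuples(index=False))


def write_annotations(annot: AnnotationMap, path) -> None:
    rows = [
        (g, t)
        for g, ts in sorted(annot.gene_to_terms.items())
        for t in sorted(ts)
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path) -> pd.DataFrame:
    """Read an expression (e.g. RPKM) TSV: genes x samples, floats."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
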