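"""Sample-transcriptome trajectory embeddings and leap/lull statistics.

Each whole-transcriptome sample is treated as a point; a time course is a
trajectory through transcriptome space.  Two 2-D embeddings are provided:

* PCA on per-gene mean-centered expression (no unit-variance scaling by
  default, preserving amplitude structure; scaling is a flag);
* metric MDS by SMACOF stress majorization on 1 - |Spearman rho|
  dissimilarities, started from deterministic classical (Torgerson)
  scaling so results are reproducible without randomness.

Replicate centroids per (condition, time point) turn the embedding into an
ordered trajectory; consecutive centroid distances quantify "leaps"
(abrupt transcriptome shifts) versus "lulls" (gradual change).  A step is
labeled a leap when its distance exceeds median + c * MAD of the
condition's step distances (c = 2 by default) — a robust quantitative
stand-in for what is otherwise read off a plot by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import SampleTable

__all__ = [
    "TrajectoryEmbedding",
    "GapProfile",
    "ClusterResult",
    "pca_embed",
    "spearman_distance",
    "mds_embed",
    "centroids_and_gaps",
    "correlation_cluster",
]


@dataclass(frozen=True)
class TrajectoryEmbedding:
    """2-D sample coordinates with method-specific quality measures.

    ``variance_fractions`` (PC1, PC2 shares of total variance) is set for
    PCA; ``stress`` (final normalized Kruskal stress-1) and ``converged``
    for MDS.  ``centroids`` holds per-(condition, time) replicate-mean
    coordinates when a sample table was supplied.  Axis units are
    arbitrary.
    """

    coords: pd.DataFrame  # index sample_id, columns dim1, dim2
    method: str
    variance_fractions: tuple[float, float] | None = None
    stress: float | None = None
    stress_trace: tuple[float, ...] | None = None
    converged: bool | None = None
    centroids: pd.DataFrame | None = None


@dataclass(frozen=True)
class GapProfile:
    """Consecutive centroid displacements along one condition's time course.

    ``steps`` has one row per consecutive time-point pair: t_from, t_to,
    distance, dt_h, rate (distance per hour) and a leap/lull label.
    """

    condition: str
    steps: pd.DataFrame
    median_distance: float
    mad_distance: float
    c: float


def _centroids(coords: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    # samples outside the embedding are ignored: a table may describe more
    # conditions than were embedded
    df = samples.df.merge(
        coords, left_on="sample_id", right_index=True, how="inner"
    )
    cent = (
        df.groupby(["condition", "time_h"], sort=True)[["dim1", "dim2"]]
        .mean()
        .reset_index()
    )
    return cent


def pca_embed(
    expr: pd.DataFrame,
    samples: SampleTable | None = None,
    *,
    scale: bool = False,
) -> TrajectoryEmbedding:
    """Project samples on the top-2 principal axes of the expression matrix.

    Genes are mean-centered (and optionally scaled to unit variance); the
    samples x genes matrix is then decomposed by SVD.  Variance fractions
    are reported against the total variance across all components.  Each
    axis is oriented so the earliest time point (or the first sample, if no
    sample table is given) has a non-positive coordinate — signs are
    mathematically arbitrary and this fixes them reproducibly.
    """
    if expr.shape[1] < 3:
        raise ValueError("PCA embedding needs >= 3 samples")
    if expr.shape[0] < 2:
        raise ValueError("PCA embedding needs >= 2 genes")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if (s > s[0] * 1e-12).sum() < 2:
        raise ValueError("expression matrix has rank < 2; cannot embed in 2-D")
    coords = U[:, :2] * s[:2]
    total = (s**2).sum()
    fractions = (float(s[0] ** 2 / total), float(s[1] ** 2 / total))

    coords = pd.DataFrame(
        coords, index=expr.columns, columns=["dim1", "dim2"]
    )
    # sign convention: earliest-time samples sit at non-positive coordinates
    if samples is not None:
        st = samples.df[samples.df["sample_id"].isin(coords.index)]
        earliest = st.loc[st["time_h"] == st["time_h"].min(), "sample_id"]
        anchor = coords.loc[earliest].mean(axis=0)
    else:
        anchor = coords.iloc[0]
    for dim in ("dim1", "dim2"):
        if anchor[dim] > 0:
            coords[dim] = -coords[dim]

    cent = _centroids(coords, samples) if samples is not None else None
    return TrajectoryEmbedding(
        coords=coords,
        method="pca",
        variance_fractions=fractions,
        centroids=cent,
    )


def spearman_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise transcriptional distance 1 - |Spearman rho| between samples.

    Ranks use average ranks for ties.  Symmetric, zero diagonal, values in
    [0, 1].  A sample with a constant profile (rho undefined) is an error.
    """
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes to rank-correlate samples")
    vals = expr.to_numpy(dtype=float)
    constant = vals.std(axis=0) == 0
    if constant.any():
        bad = expr.columns[constant].tolist()
        raise ValueError(f"constant expression profile for samples: {bad[:5]}")
    ranks = rankdata(vals, axis=0)  # average ranks
    rho = np.corrcoef(ranks, rowvar=False)
    d = 1.0 - np.abs(rho)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def _classical_scaling(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Torgerson classical scaling start: double-centered -D^2/2 eigvectors."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:ndim]
    w_top = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(w_top)
    if X.shape[1] < ndim:  # degenerate: pad
        X = np.hstack([X, np.zeros((n, ndim - X.shape[1]))])
    return X


def _stress1(D: np.ndarray, X: np.ndarray) -> float:
    d = squareform(pdist(X))
    iu = np.triu_indices_from(D, k=1)
    denom = (D[iu] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d[iu] - D[iu]) ** 2).sum() / denom))


def mds_embed(
    distances: pd.DataFrame,
    samples: SampleTable | None = None,
    *,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> TrajectoryEmbedding:
    """Metric 2-D MDS by SMACOF majorization from a classical-scaling start.

    The Guttman transform guarantees a non-increasing raw stress, hence a
    non-increasing normalized stress-1 trace; iteration stops when the
    relative stress decrease falls below ``tol``.  The start is
    deterministic, so ``seed`` is accepted only for interface symmetry.
    Non-convergence within ``max_iter`` returns the best configuration with
    ``converged=False``.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance table must be square and symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    n = D.shape[0]
    if n < 3:
        raise ValueError("MDS embedding needs >= 3 points")

    X = _classical_scaling(D, 2)
    trace = [_stress1(D, X)]
    converged = False
    for _ in range(max_iter):
        d = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, D / d, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        trace.append(_stress1(D, X))
        prev, cur = trace[-2], trace[-1]
        if prev - cur <= tol * max(prev, 1e-30):
            converged = True
            break

    coords = pd.DataFrame(X, index=distances.index, columns=["dim1", "dim2"])
    cent = _centroids(coords, samples) if samples is not None else None
    return TrajectoryEmbedding(
        coords=coords,
        method="mds",
        stress=trace[-1],
        stress_trace=tuple(trace),
        converged=converged,
        centroids=cent,
    )


def centroids_and_gaps(
    emb: TrajectoryEmbedding,
    samples: SampleTable,
    condition: str,
    *,
    c: float = 2.0,
) -> GapProfile:
    """Consecutive centroid distances with leap/lull labels for one condition.

    A step is a leap if its distance exceeds median + c * MAD (MAD = median
    absolute deviation, unscaled) of the condition's step distances.
    Labels are invariant to a global rescaling of the coordinates.
    """
    cond_samples = samples.for_condition(condition)
    times = np.sort(cond_samples["time_h"].unique())
    if len(times) < 3:
        raise ValueError(f"condition {condition!r} has < 3 time points")
    missing = set(cond_samples["sample_id"]) - set(emb.coords.index)
    if missing:
        raise ValueError(f"samples missing from embedding: {sorted(missing)[:5]}")
    cent = _centroids(
        emb.coords.loc[cond_samples["sample_id"]],
        SampleTable(cond_samples),
    ).set_index("time_h")

    xy = cent.loc[times, ["dim1", "dim2"]].to_numpy()
    dist = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(times)
    med = float(np.median(dist))
    mad = float(np.median(np.abs(dist - med)))
    labels = np.where(dist > med + c * mad, "leap", "lull")
    steps = pd.DataFrame(
        {
            "t_from": times[:-1],
            "t_to": times[1:],
            "distance": dist,
            "dt_h": dt,
            "rate": dist / dt,
            "label": labels,
        }
    )
    return GapProfile(
        condition=condition,
        steps=steps,
        median_distance=med,
        mad_distance=mad,
        c=c,
    )


@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage dendrogram of samples with bootstrap support.

    ``linkage_matrix`` is a scipy linkage over ``labels``;
    ``support`` maps each internal node's member-set (frozenset of sample
    ids) to the fraction of gene-resampled bootstrap trees containing the
    same cluster.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    support: dict[frozenset, float]
    n_boot: int


def _clusters_of(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        m = members[int(a)] | members[int(b)]
        members[n + k] = m
        out.append(m)
    return out


def _abs_spearman_dist(vals: np.ndarray) -> np.ndarray:
    ranks = rankdata(vals, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(ranks, axis=0)
    norms[norms == 0] = 1.0  # constant bootstrap profile: treat rho as 0
    rho = (ranks / norms).T @ (ranks / norms)
    d = 1.0 - np.abs(np.clip(rho, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def correlation_cluster(
    expr: pd.DataFrame, n_boot: int = 200, seed: int = 0
) -> ClusterResult:
    """Average-linkage clustering of samples on 1 - |Spearman| distances.

    Node support is the ordinary bootstrap proportion: the fraction of
    gene-resampled replicate trees that reproduce the node's exact sample
    membership.  (No multiscale/AU correction.)
    """
    if expr.shape[1] < 3:
        raise ValueError("clustering needs >= 3 samples")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = [str(c) for c in expr.columns]
    D = spearman_distance(expr).to_numpy()
    Z = linkage(squareform(D, checks=False), method="average")
    clusters = _clusters_of(Z, labels)
    # skip the root: present in every tree by construction
    scored = [c for c in clusters if len(c) < len(labels)]

    rng = np.random.default_rng(seed)
    vals = expr.to_numpy(dtype=float)
    hits = {c: 0 for c in scored}
    for _ in range(n_boot):
        idx = rng.integers(0, vals.shape[0], size=vals.shape[0])
        Db = _abs_spearman_dist(vals[idx])
        Zb = linkage(squareform(Db, checks=False), method="average")
        boot_clusters = set(_clusters_of(Zb, labels))
        for c in scored:
            if c in boot_clusters:
                hits[c] += 1
    support = {c: hits[c] / n_boot for c in scored}
    support[frozenset(labels)] = 1.0
    return ClusterResult(
        labels=tuple(labels), linkage_matrix=Z, support=support, n_boot=n_boot
    )
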