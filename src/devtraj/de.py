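"""Negative-binomial differential expression between time points.

The unit of inference is a pair of time points within one condition.  For
each gene a likelihood-ratio test compares NB models with a common mean
versus separate group means, with per-sample library-size offsets and a
fixed per-gene dispersion.  Dispersion is never estimated per pair (groups
have 2–3 replicates): method-of-moments estimates are computed from the
full time series, then shrunk in log space toward a parametric
mean–dispersion trend (a0 + a1 / mean), and the shrunk values are reused
for every comparison.  P-values are Benjamini–Hochberg adjusted across
genes within each comparison.

The engine is pluggable: any per-pair DE table with the same columns can be
ingested via :func:`calls_from_table` (e.g. output of an external
empirical-Bayes tool), and every downstream consumer (k-hop accounting,
enrichment) operates on the table alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, SampleTable

__all__ = [
    "DECalls",
    "size_factors",
    "estimate_dispersions",
    "pairwise_test",
    "all_pairs",
    "calls_from_table",
]

_POISSON_PHI = 1e-8  # below this, use the Poisson limit exactly
_CALL_COLUMNS = [
    "gene_id",
    "time_a",
    "time_b",
    "p",
    "fdr",
    "de",
    "direction",
    "log2fc",
]


@dataclass(frozen=True)
class DECalls:
    """DE calls over one or more time-point pairs of a single condition.

    ``table`` is long-format with columns gene_id, time_a, time_b (with
    time_a < time_b), p, fdr, de (bool at the stated threshold), direction
    ('up' if the later time has the higher normalized mean, 'down' if
    lower, 'none' for exact ties) and log2fc (later vs earlier,
    pseudocount-protected).
    """

    condition: str
    fdr_threshold: float
    table: pd.DataFrame

    def pair(self, t_a: float, t_b: float) -> pd.DataFrame:
        """Calls for an ordered pair; directions flip if t_a > t_b."""
        lo, hi = min(t_a, t_b), max(t_a, t_b)
        sub = self.table[
            (self.table["time_a"] == lo) & (self.table["time_b"] == hi)
        ]
        if sub.empty:
            raise KeyError(f"no calls for pair ({t_a}, {t_b})")
        sub = sub.copy()
        if t_a > t_b:
            flip = {"up": "down", "down": "up", "none": "none"}
            sub["direction"] = sub["direction"].map(flip)
            sub["log2fc"] = -sub["log2fc"]
            sub["time_a"], sub["time_b"] = t_a, t_b
        return sub

    def de_genes(self, t_a: float, t_b: float, direction: str | None = None) -> set:
        sub = self.pair(t_a, t_b)
        sub = sub[sub["de"]]
        if direction is not None:
            sub = sub[sub["direction"] == direction]
        return set(sub["gene_id"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, scaled to geometric mean 1.

    Each sample's factor is the median ratio of its counts to the per-gene
    geometric mean over samples (genes expressed everywhere).  Unlike raw
    column totals this is robust to composition shifts — a block of
    strongly up-regulated genes does not drag every other gene into
    apparent down-regulation.  Falls back to total counts when too few
    genes are expressed in all samples.
    """
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total reads: {bad}")
    vals = counts.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if all_pos.sum() >= 10:
        logs = np.log(vals[all_pos])
        log_geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - log_geo, axis=0))
    else:
        sf = (totals / totals.mean()).to_numpy()
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: CountMatrix,
    samples: SampleTable,
    condition: str,
    *,
    prior_df: float = 50.0,
) -> pd.Series:
    """Trend-shrunk per-gene NB dispersions from the full time series.

    Method-of-moments gene estimates (pooled within time-point groups that
    have >= 2 replicates) are shrunk in log space toward the least-squares
    parametric trend phi(mu) = a0 + a1/mu, with weight residual_df /
    (residual_df + prior_df).  Genes without a positive moment estimate take
    the trend value.

    The default prior is strong (prior_df = 50): with 2-3 replicates per
    time point the per-gene moment estimates carry only a few degrees of
    freedom, and lightly-shrunk values make the chi-squared LRT tail
    anti-conservative (genes with luckily small variance estimates dominate
    the extreme tail).  Near-trend shrinkage keeps null p-values calibrated
    at the far tail where BH-FDR operates.
    """
    cond = samples.for_condition(condition)
    sub = counts.counts[cond["sample_id"].tolist()]
    s = size_factors(counts.counts)[sub.columns].to_numpy()
    z = sub.to_numpy(dtype=float) / s  # normalized counts

    groups = [
        np.flatnonzero((cond["time_h"] == t).to_numpy())
        for t in cond["time_h"].unique()
    ]
    rep_groups = [g for g in groups if len(g) >= 2]
    if not rep_groups:
        raise ValueError(
            "no time point has >= 2 replicates; cannot estimate dispersion"
        )
    rss = np.zeros(sub.shape[0])
    shot = np.zeros(sub.shape[0])
    df = 0
    for g in rep_groups:
        zg = z[:, g]
        qhat = zg.mean(axis=1)
        rss += ((zg - qhat[:, None]) ** 2).sum(axis=1)
        # shot-noise part of E[(z - qhat)^2]: Var[z_j] = q/s_j + phi q^2
        shot += (qhat[:, None] / s[g]).sum(axis=1) * (len(g) - 1) / len(g)
        df += len(g) - 1
    qbar = z.mean(axis=1)
    var_z = rss / df  # pooled within-group variance of normalized counts
    shot_mean = shot / df
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = np.where(qbar > 0, (var_z - shot_mean) / qbar**2, np.nan)

    # trend fit uses ALL finite moment estimates, negatives included:
    # conditioning on phi_mom > 0 would upward-bias the trend and make the
    # test conservative (the estimates are mean-unbiased, not sign-definite)
    ok = np.isfinite(phi_mom) & (qbar > 0)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / qbar[ok]])
        coef, *_ = np.linalg.lstsq(A, phi_mom[ok], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        if a0 == 0 and a1 == 0:
            a0 = max(float(np.median(phi_mom[ok])), 1e-6)
    else:
        a0 = max(float(np.nanmedian(phi_mom)) if ok.any() else 0.01, 1e-6)
        a1 = 0.0
    trend = a0 + a1 / np.where(qbar > 0, qbar, 1.0)
    trend = np.clip(trend, 1e-6, None)

    w = df / (df + prior_df)
    phi_gene = np.clip(phi_mom, 1e-6, None)
    log_shrunk = np.where(
        np.isfinite(phi_mom) & (phi_mom > 0),
        w * np.log(phi_gene) + (1 - w) * np.log(trend),
        np.log(trend),
    )
    return pd.Series(np.exp(log_shrunk), index=counts.gene_ids, name="dispersion")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; phi is per-gene (column vector-safe)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], y.shape)
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(y.shape)
    pois = phi < _POISSON_PHI
    safe_mu = np.where(mu > 0, mu, 1.0)
    ll_pois = y * np.log(safe_mu) - mu - gammaln(y + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 / np.where(pois, 1.0, phi)
        ll_nb = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + safe_mu))
            + y * np.log(safe_mu / (r + safe_mu))
        )
    out = np.where(pois, ll_pois, ll_nb)
    # mu == 0: pmf is 1 at y = 0 (contributes 0); y > 0 impossible under fit
    out = np.where(mu == 0, np.where(y == 0, 0.0, -np.inf), out)
    return out.sum(axis=1)


def _fit_group_mean(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """Per-gene MLE of the group mean q (mu_j = s_j * q) at fixed dispersion.

    Newton on log q, vectorized across genes.  Genes with zero group total
    have q = 0.  For Poisson-limit genes the closed form sum(y)/sum(s) is
    exact and Newton converges to it.
    """
    tot = y.sum(axis=1)
    q = np.where(tot > 0, tot / s.sum(), 0.0)
    active = tot > 0
    if not active.any():
        return q
    u = np.log(q[active])
    ya = y[active]
    ph = phi[active][:, None]
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(u)[:, None]
        w = 1.0 + ph * mu
        grad = ((ya - mu) / w).sum(axis=1)
        hess = -(mu * (1.0 + ph * ya) / w**2).sum(axis=1)
        step = np.where(hess < 0, grad / hess, 0.0)
        step = np.clip(step, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    q[active] = np.exp(u)
    return q


def _lrt_pair(
    y_a: np.ndarray,
    y_b: np.ndarray,
    s_a: np.ndarray,
    s_b: np.ndarray,
    phi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """LRT statistic and p-value for separate vs common group means."""
    y_all = np.hstack([y_a, y_b])
    s_all = np.hstack([s_a, s_b])
    q0 = _fit_group_mean(y_all, s_all, phi)
    qa = _fit_group_mean(y_a, s_a, phi)
    qb = _fit_group_mean(y_b, s_b, phi)
    ll0 = _nb_loglik(y_all, s_all[None, :] * q0[:, None], phi)
    ll1 = _nb_loglik(y_a, s_a[None, :] * qa[:, None], phi) + _nb_loglik(
        y_b, s_b[None, :] * qb[:, None], phi
    )
    stat = np.clip(2.0 * (ll1 - ll0), 0.0, None)
    p = chi2.sf(stat, df=1)
    allzero = y_all.sum(axis=1) == 0
    p = np.where(allzero, 1.0, p)
    return stat, p


def pairwise_test(
    counts: CountMatrix,
    samples: SampleTable,
    t_a: float,
    t_b: float,
    *,
    condition: str | None = None,
    fdr: float = 0.01,
    dispersion: pd.Series | None = None,
) -> DECalls:
    """NB likelihood-ratio DE test between two time points of one condition.

    ``dispersion`` (a per-gene Series, e.g. from
    :func:`estimate_dispersions` on the full series) is reused across
    comparisons; if omitted it is estimated from the condition's full
    series.  Direction is resolved relative to the later time point;
    fold changes use a 0.5 pseudocount on normalized group means.
    """
    if condition is None:
        conds = samples.conditions
        if len(conds) != 1:
            raise ValueError("condition must be given when table has several")
        condition = conds[0]
    cond = samples.for_condition(condition)
    have = set(cond["time_h"])
    for t in (t_a, t_b):
        if t not in have:
            raise ValueError(f"time point {t} absent from condition {condition!r}")
    ids_a = cond.loc[cond["time_h"] == t_a, "sample_id"].tolist()
    ids_b = cond.loc[cond["time_h"] == t_b, "sample_id"].tolist()
    if dispersion is None:
        # always from the full series: per-pair groups are too small
        dispersion = estimate_dispersions(counts, samples, condition)
    phi = dispersion.reindex(counts.gene_ids).to_numpy(dtype=float)
    if np.isnan(phi).any():
        raise ValueError("dispersion series does not cover all genes")

    sf = size_factors(counts.counts)
    y_a = counts.counts[ids_a].to_numpy(dtype=float)
    y_b = counts.counts[ids_b].to_numpy(dtype=float)
    s_a = sf[ids_a].to_numpy()
    s_b = sf[ids_b].to_numpy()

    _, p = _lrt_pair(y_a, y_b, s_a, s_b, phi)
    rej, p_adj, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    de = p_adj <= fdr

    m_a = (y_a / s_a).mean(axis=1)
    m_b = (y_b / s_b).mean(axis=1)
    # orient to the later time point
    if t_a <= t_b:
        m_lo, m_hi = m_a, m_b
        lo, hi = t_a, t_b
    else:
        m_lo, m_hi = m_b, m_a
        lo, hi = t_b, t_a
    log2fc = np.log2((m_hi + 0.5) / (m_lo + 0.5))
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))

    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "time_a": lo,
            "time_b": hi,
            "p": p,
            "fdr": p_adj,
            "de": de,
            "direction": direction,
            "log2fc": log2fc,
        }
    )
    return DECalls(condition=condition, fdr_threshold=fdr, table=table)


def all_pairs(
    counts: CountMatrix,
    samples: SampleTable,
    condition: str,
    *,
    fdr: float = 0.01,
) -> DECalls:
    """DE calls for every unordered time-point pair of one condition.

    Each of the T*(T-1)/2 comparisons is computed once; both orders are
    available through :meth:`DECalls.pair`, which flips directions.
    Dispersions and size factors are shared across all comparisons.
    """
    times = samples.times(condition)
    if len(times) < 2:
        raise ValueError(f"condition {condition!r} has < 2 time points")
    disp = estimate_dispersions(counts, samples, condition)
    tables = [
        pairwise_test(
            counts, samples, ta, tb, condition=condition, fdr=fdr, dispersion=disp
        ).table
        for ta, tb in combinations(times, 2)
    ]
    return DECalls(
        condition=condition,
        fdr_threshold=fdr,
        table=pd.concat(tables, ignore_index=True),
    )


def calls_from_table(
    table: pd.DataFrame, condition: str, fdr_threshold: float = 0.01
) -> DECalls:
    """Ingest an externally computed per-pair DE table (engine shim).

    The table must carry the standard columns (gene_id, time_a, time_b, p,
    fdr, de, direction, log2fc) with time_a < time_b; any engine producing
    them (e.g. an empirical-Bayes posterior pipeline) can drive the k-hop
    and enrichment stages.
    """
    missing = [c for c in _CALL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if (table["time_a"] >= table["time_b"]).any():
        raise ValueError("DE table rows must have time_a < time_b")
    return DECalls(
        condition=condition,
        fdr_threshold=fdr_threshold,
        table=table[_CALL_COLUMNS].copy(),
    )
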