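"""Developmental-time prediction from whole-transcriptome profiles.

A linear model maps a transcriptome to a developmental time: expression is
per-gene centered with the TRAINING means, projected on the top-q principal
axes of the training samples, and ordinary least squares regresses time on
the q scores.  With thousands of genes and tens of samples a direct OLS on
genes is underdetermined; principal-component regression makes the fit
well-posed while remaining linear in expression.  ``q='auto'`` picks q by
leave-one-timepoint-out rank accuracy on the training set.

Models trained on one experiment transfer to another (both directions);
accuracy is scored by the Spearman rank correlation between predicted and
true times — the developmental ORDER of samples, not the clock values,
since conditions may run on different time scales.  The mean signed offset
(predicted - true) estimates any temporal lag between conditions: a
negative offset on the test experiment means the training experiment
reaches the same transcriptional states earlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import SampleTable

__all__ = ["TimeModel", "fit_time_model", "predict_times", "predict_and_score"]


@dataclass(frozen=True)
class TimeModel:
    """Linear developmental-time predictor on principal-component scores."""

    gene_ids: tuple[str, ...]
    gene_means: np.ndarray  # training per-gene centering values
    components: np.ndarray  # genes x q projection basis
    coef: np.ndarray  # q linear coefficients
    intercept: float
    q: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")


def _pc_basis(X: np.ndarray, q: int) -> np.ndarray:
    """Top-q right singular vectors (genes x q) of centered samples x genes."""
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if q > rank:
        raise ValueError(f"q={q} exceeds training matrix rank {rank}")
    return Vt[:q].T


def _fit_fixed_q(
    X: np.ndarray, times: np.ndarray, q: int
) -> tuple[np.ndarray, np.ndarray, float]:
    basis = _pc_basis(X, q)
    scores = X @ basis
    A = np.column_stack([np.ones(len(times)), scores])
    beta, *_ = np.linalg.lstsq(A, times, rcond=None)
    return basis, beta[1:], float(beta[0])


def fit_time_model(
    expr: pd.DataFrame,
    samples: SampleTable,
    *,
    q: int | str = "auto",
    q_max: int = 10,
) -> TimeModel:
    """Fit time ~ top-q PC scores of the training expression matrix.

    ``expr`` is genes x samples and must cover every training sample.  With
    ``q='auto'``, q in 1..min(q_max, n-2) is chosen by leave-one-timepoint-
    out validation: all samples of one time point are held out at a time
    and q maximizing the Spearman rank correlation of the pooled held-out
    predictions wins (smallest q on ties).
    """
    st = samples.df
    if len(st) < 4:
        raise ValueError("need >= 4 training samples")
    missing = set(st["sample_id"]) - set(expr.columns)
    if missing:
        raise ValueError(f"expression missing training samples: {sorted(missing)[:5]}")
    X_full = expr[st["sample_id"]].to_numpy(dtype=float).T  # samples x genes
    times = st["time_h"].to_numpy(dtype=float)
    n = len(times)

    if q == "auto":
        best_q, best_rho = 1, -np.inf
        uniq_times = np.unique(times)
        for q_try in range(1, min(q_max, n - 2) + 1):
            preds = np.empty(n)
            ok = True
            for t in uniq_times:
                hold = times == t
                Xtr = X_full[~hold]
                mu = Xtr.mean(axis=0)
                try:
                    basis, coef, icpt = _fit_fixed_q(Xtr - mu, times[~hold], q_try)
                except ValueError:
                    ok = False
                    break
                preds[hold] = (X_full[hold] - mu) @ basis @ coef + icpt
            if not ok:
                break
            rho = spearmanr(preds, times).statistic
            if np.isfinite(rho) and rho > best_rho + 1e-12:
                best_q, best_rho = q_try, rho
        q = best_q
    q = int(q)
    if q >= n:
        raise ValueError(f"q={q} must be < n_samples={n}")

    mu = X_full.mean(axis=0)
    basis, coef, icpt = _fit_fixed_q(X_full - mu, times, q)
    return TimeModel(
        gene_ids=tuple(str(g) for g in expr.index),
        gene_means=mu,
        components=basis,
        coef=coef,
        intercept=icpt,
        q=q,
    )


def predict_times(model: TimeModel, expr: pd.DataFrame) -> pd.Series:
    """Predicted developmental time for each column (sample) of ``expr``.

    The test matrix must contain every model gene; it is centered with the
    TRAINING means so predictions live on the training clock.
    """
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"test expression missing model genes: {missing[:5]}")
    X = expr.loc[list(model.gene_ids)].to_numpy(dtype=float).T
    preds = (X - model.gene_means) @ model.components @ model.coef + model.intercept
    return pd.Series(preds, index=expr.columns, name="predicted_time_h")


def predict_and_score(
    model: TimeModel, expr: pd.DataFrame, samples: SampleTable
) -> tuple[pd.DataFrame, float, float]:
    """Predict test-sample times and score rank agreement with truth.

    Returns (per-sample table, Spearman rho, mean signed offset).  The
    score uses average ranks for replicate ties; the offset is
    mean(predicted - true) in hours and carries the sign of any lag of the
    test condition relative to the training condition's clock.
    """
    st = samples.df
    preds = predict_times(model, expr[st["sample_id"]])
    truth = st.set_index("sample_id")["time_h"]
    table = pd.DataFrame(
        {
            "sample_id": preds.index,
            "true_time_h": truth.loc[preds.index].to_numpy(),
            "predicted_time_h": preds.to_numpy(),
        }
    )
    rho = float(
        spearmanr(table["predicted_time_h"], table["true_time_h"]).statistic
    )
    offset = float(
        (table["predicted_time_h"] - table["true_time_h"]).mean()
    )
    return table, rho, offset
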