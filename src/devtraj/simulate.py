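"""Synthetic staged developmental time courses.

Generates two-condition RNA-seq count matrices with the statistical
structure the downstream analysis assumes: a small number of abrupt
transcriptome shifts ("leaps") at stage boundaries separating blocks of
gradual within-stage drift, negative-binomial count noise, log-normal
library-size variation, and an optional temporal lag of the second
condition relative to the first (the cAMP-pulsed suspension cells of the
motivating system run ~4 h ahead of filter-developed cells).

The default :class:`SimConfig` mirrors the study design the package was
built around: one condition sampled hourly 0–12 h then two-hourly to 24 h
(19 time points, 2 replicates) and a second sampled hourly 0–6 h then
two-hourly to 12 h (10 time points, 3 replicates, one sample missing),
giving 38 + 29 = 67 samples over ~12,000 genes.

Counts are drawn as NB(mean, dispersion) with the mean/dispersion
parameterization var = mu + phi * mu**2, so dispersion -> 0 recovers the
Poisson limit.  The expected count is

    mean(g, s) = library_factor(s) * program_mean(g, t(s)) * length_kb(g)

so RPKM normalization recovers the programmed abundances up to a
per-sample constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable

__all__ = ["StageProgram", "SimConfig", "generate", "random_program"]

# paper-design sampling grids (hours)
FILTER_TIMES = tuple(range(0, 13)) + (14, 16, 18, 20, 22, 24)  # 19 points
SUSPENSION_TIMES = tuple(range(0, 7)) + (8, 10, 12)  # 10 points


@dataclass(frozen=True)
class StageProgram:
    """Stage-structured per-gene expression program over developmental time.

    ``stage_boundaries_h`` partition ``[t_min, t_max]`` into stages.  Genes
    in ``leap_genes`` jump multiplicatively at their designated boundaries;
    all genes additionally drift within stages at a per-gene exponential
    rate whose magnitude is bounded by ``drift_rate`` (fractional change
    per hour).

    Parameters
    ----------
    t_min, t_max
        Domain of the program in hours.
    stage_boundaries_h
        Strictly increasing boundary times, all inside ``(t_min, t_max)``.
    base_mean
        Per-gene baseline abundance (arbitrary units), length ``n_genes``.
    leap_log2fc
        (n_genes, n_boundaries) log2 fold-changes applied at each boundary;
        rows of zeros for non-leap genes.
    drift_log_rate
        Per-gene signed log-linear drift rate (1/h).
    """

    t_min: float
    t_max: float
    stage_boundaries_h: tuple[float, ...]
    base_mean: np.ndarray
    leap_log2fc: np.ndarray
    drift_log_rate: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.stage_boundaries_h, dtype=float)
        if len(b) and (np.any(np.diff(b) <= 0)):
            raise ValueError("stage boundaries must be strictly increasing")
        if len(b) and (b[0] <= self.t_min or b[-1] >= self.t_max):
            raise ValueError("stage boundaries must lie inside (t_min, t_max)")
        if np.any(self.base_mean < 0):
            raise ValueError("per-gene baseline means must be >= 0")
        if self.leap_log2fc.shape != (len(self.base_mean), len(b)):
            raise ValueError("leap_log2fc must be (n_genes, n_boundaries)")

    @property
    def n_genes(self) -> int:
        return len(self.base_mean)

    @property
    def leap_genes(self) -> np.ndarray:
        """Boolean mask of genes with a non-zero jump at any boundary."""
        return np.any(self.leap_log2fc != 0, axis=1)

    def mean_at(self, t: float) -> np.ndarray:
        """Expected abundance of every gene at time ``t`` (clipped to domain)."""
        t = float(np.clip(t, self.t_min, self.t_max))
        b = np.asarray(self.stage_boundaries_h, dtype=float)
        crossed = b <= t
        log2_jump = self.leap_log2fc[:, crossed].sum(axis=1) if len(b) else 0.0
        return (
            self.base_mean
            * np.exp2(log2_jump)
            * np.exp(self.drift_log_rate * (t - self.t_min))
        )


def random_program(
    n_genes: int,
    *,
    t_min: float = 0.0,
    t_max: float = 24.0,
    stage_boundaries_h: Sequence[float] = (8.0, 16.0),
    leap_fraction: float = 0.1,
    leap_log2fc: float = 2.0,
    drift_rate: float = 0.02,
    rng: np.random.Generator | None = None,
) -> StageProgram:
    """Draw a random stage program.

    ``leap_fraction`` of genes jump at one (randomly chosen) boundary by
    ``±leap_log2fc`` log2 units; every gene drifts at a rate uniform in
    ``[-drift_rate, drift_rate]`` per hour.  Baselines are log-normal.
    """
    rng = np.random.default_rng() if rng is None else rng
    boundaries = tuple(float(b) for b in stage_boundaries_h)
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes)
    jumps = np.zeros((n_genes, len(boundaries)))
    if boundaries and leap_fraction > 0 and leap_log2fc != 0:
        n_leap = int(round(leap_fraction * n_genes))
        leap_idx = rng.choice(n_genes, size=n_leap, replace=False)
        which = rng.integers(0, len(boundaries), size=n_leap)
        signs = rng.choice([-1.0, 1.0], size=n_leap)
        jumps[leap_idx, which] = signs * leap_log2fc
    drift = rng.uniform(-drift_rate, drift_rate, size=n_genes)
    return StageProgram(
        t_min=t_min,
        t_max=t_max,
        stage_boundaries_h=boundaries,
        base_mean=base,
        leap_log2fc=jumps,
        drift_log_rate=drift,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study design and noise model for :func:`generate`.

    Defaults state the motivating design: 19 hourly/two-hourly time points
    with 2 replicates for condition 1 ("filter"), 10 for condition 2
    ("suspension") with 3 replicates and the (12 h, replicate 3) sample
    missing; NB dispersion 0.05; ~25% log-normal library-size spread; no
    lag.  ``condition2_lag_h`` shifts condition 2's program evaluation to
    ``t + lag`` (truncated to the program domain), emulating one condition
    running ahead of the other.
    """

    n_genes: int = 12000
    times_1: tuple[float, ...] = FILTER_TIMES
    times_2: tuple[float, ...] = SUSPENSION_TIMES
    replicates_1: int = 2
    replicates_2: int = 3
    condition_1: str = "filter"
    condition_2: str = "suspension"
    missing: tuple[tuple[str, float, str], ...] = (("suspension", 12.0, "r3"),)
    dispersion: float = 0.05
    library_log_sigma: float = 0.25
    mean_library_factor: float = 1.0
    condition2_lag_h: float = 0.0
    gene_lengths_bp: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if max(self.replicates_1, self.replicates_2) < 2:
            raise ValueError("at least one condition needs >= 2 replicates")
        if len(self.times_1) < 2 or len(self.times_2) < 2:
            raise ValueError("each condition needs >= 2 time points")


def _design_rows(cfg: SimConfig) -> list[tuple[str, str, float, str]]:
    missing = set(cfg.missing)
    rows = []
    for cond, times, nrep in (
        (cfg.condition_1, cfg.times_1, cfg.replicates_1),
        (cfg.condition_2, cfg.times_2, cfg.replicates_2),
    ):
        for t in times:
            for r in range(1, nrep + 1):
                rep = f"r{r}"
                if (cond, float(t), rep) in missing:
                    continue
                sid = f"{cond}_{t:g}h_{rep}"
                rows.append((sid, cond, float(t), rep))
    return rows


def generate(
    config: SimConfig, program: StageProgram
) -> tuple[CountMatrix, SampleTable, dict]:
    """Simulate counts for the two-condition design described by ``config``.

    Returns the count matrix, the sample table, and a truth record with the
    programmed stage boundaries, the leap-gene ids, each sample's true
    program-evaluation time (including any lag) and its library factor.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    lag = config.condition2_lag_h
    if lag and (
        min(config.times_2) + lag > program.t_max
        or max(config.times_2) + lag < program.t_min
    ):
        raise ValueError(
            "condition 2 lag pushes the whole series outside the program domain"
        )

    rows = _design_rows(config)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")
    if config.gene_lengths_bp is not None:
        lengths = np.asarray(config.gene_lengths_bp, dtype=np.int64)
        if len(lengths) != config.n_genes:
            raise ValueError("gene_lengths_bp length must equal n_genes")
    else:
        # uniform 500-5000 bp: exercises the per-kilobase RPKM term
        lengths = rng.integers(500, 5001, size=config.n_genes)
    length_kb = lengths / 1000.0

    lib = config.mean_library_factor * rng.lognormal(
        mean=-0.5 * config.library_log_sigma**2,
        sigma=config.library_log_sigma,
        size=len(rows),
    )

    counts = np.empty((config.n_genes, len(rows)), dtype=np.int64)
    true_eval_time = {}
    for j, (sid, cond, t, _rep) in enumerate(rows):
        t_eval = t + lag if cond == config.condition_2 else t
        t_eval = float(np.clip(t_eval, program.t_min, program.t_max))
        true_eval_time[sid] = t_eval
        mu = lib[j] * program.mean_at(t_eval) * length_kb
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=[r[0] for r in rows])
    cm = CountMatrix(counts_df, pd.Series(lengths, index=gene_ids))
    st = SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "condition", "time_h", "replicate"])
    )
    truth = {
        "stage_boundaries_h": list(program.stage_boundaries_h),
        "leap_genes": gene_ids[program.leap_genes].tolist(),
        "leap_log2fc_by_boundary": {
            f"{b:g}": gene_ids[program.leap_log2fc[:, i] != 0].tolist()
            for i, b in enumerate(program.stage_boundaries_h)
        },
        "true_eval_time_h": true_eval_time,
        "library_factor": {r[0]: float(lib[j]) for j, r in enumerate(rows)},
        "condition2_lag_h": lag,
        "dispersion": config.dispersion,
    }
    return cm, st, truth
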