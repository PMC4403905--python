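"""k-hop windowed accounting of differential-expression calls.

For each reference time point t of a condition, DE genes are counted in
windows of k = 1..k_max hops: up-regulated genes looking BACK in time
(t versus t-1 hop, t-2 hops, ...) and down-regulated genes looking FORWARD
(t versus t+1 hop, ...).  A gene DE at several hops from the same reference
is assigned only to the smallest hop ("smallest-delta deduplication"), so
the bins for a fixed (reference, direction) partition the union of DE genes
over the scanned hops.

A "hop" is by default a step between ADJACENT SAMPLED time points — after
the sampling interval widens from 1 h to 2 h, one hop spans 2 h of clock
time.  ``hop_mode='clock'`` instead scans time points exactly k clock-hours
away, leaving bins empty where no sample exists at that offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DECalls
from .io import SampleTable

__all__ = ["KHopTable", "khop_counts", "label_intervals"]


@dataclass(frozen=True)
class KHopTable:
    """Deduplicated DE-gene counts per (reference time, hop, direction).

    ``counts`` columns: condition, ref_time, k, direction, n_genes.
    ``gene_sets`` maps (ref_time, k, direction) -> frozenset of gene ids
    (the dedup partition); the per-(ref_time, direction) union equals the
    set of genes DE at any scanned hop.
    """

    condition: str
    k_max: int
    hop_mode: str
    counts: pd.DataFrame
    gene_sets: dict[tuple[float, int, str], frozenset]

    def count(self, ref_time: float, k: int, direction: str) -> int:
        sub = self.counts[
            (self.counts["ref_time"] == ref_time)
            & (self.counts["k"] == k)
            & (self.counts["direction"] == direction)
        ]
        return int(sub["n_genes"].iloc[0]) if len(sub) else 0

    def union_size(self, ref_time: float, direction: str) -> int:
        genes: set = set()
        for (t, _, d), g in self.gene_sets.items():
            if t == ref_time and d == direction:
                genes |= g
        return len(genes)


def _hop_targets(
    times: np.ndarray, i: int, k: int, forward: bool, hop_mode: str
) -> float | None:
    """Time point k hops away from times[i], or None past the boundary."""
    if hop_mode == "index":
        j = i + k if forward else i - k
        if 0 <= j < len(times):
            return float(times[j])
        return None
    if hop_mode == "clock":
        target = times[i] + k if forward else times[i] - k
        hit = times[np.isclose(times, target)]
        return float(hit[0]) if len(hit) else None
    raise ValueError(f"unknown hop_mode {hop_mode!r}; use 'index' or 'clock'")


def khop_counts(
    calls: DECalls,
    samples: SampleTable,
    condition: str | None = None,
    *,
    k_max: int = 4,
    hop_mode: str = "index",
) -> KHopTable:
    """Count DE genes in k-hop windows with smallest-delta deduplication.

    Up-regulated genes are scanned backwards from each reference time,
    down-regulated genes forwards; each gene is counted once per
    (reference, direction), in the smallest hop where it is DE.  Hops past
    the series boundary contribute no bins, so the first time point has no
    up bins and the last no down bins.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    condition = condition or calls.condition
    times = samples.times(condition)

    rows = []
    gene_sets: dict[tuple[float, int, str], frozenset] = {}
    for i, t in enumerate(times):
        for direction, forward in (("up", False), ("down", True)):
            seen: set = set()
            for k in range(1, k_max + 1):
                other = _hop_targets(times, i, k, forward, hop_mode)
                if other is None:
                    continue
                # 'up' means the later time is higher: looking back the
                # reference is the later time; looking forward a drop after
                # the reference reads as 'down' at the later time
                if forward:
                    de = calls.de_genes(float(t), float(other), "down")
                else:
                    de = calls.de_genes(float(other), float(t), "up")
                fresh = frozenset(de - seen)
                seen |= de
                gene_sets[(float(t), k, direction)] = fresh
                rows.append(
                    {
                        "condition": condition,
                        "ref_time": float(t),
                        "k": k,
                        "direction": direction,
                        "n_genes": len(fresh),
                    }
                )
    counts = pd.DataFrame(
        rows, columns=["condition", "ref_time", "k", "direction", "n_genes"]
    )
    return KHopTable(
        condition=condition,
        k_max=k_max,
        hop_mode=hop_mode,
        counts=counts,
        gene_sets=gene_sets,
    )


def label_intervals(
    table: KHopTable,
    samples: SampleTable,
    *,
    rapid_quantile: float = 0.75,
) -> pd.DataFrame:
    """Label consecutive steps of the time course as rapid or gradual.

    Each step (t_i, t_{i+1}) is scored by its 1-hop DE total: up-regulated
    genes at reference t_{i+1} plus down-regulated genes at reference t_i.
    A step is 'rapid' when its total STRICTLY exceeds the given quantile of
    all step totals in the condition (so uniform counts yield no rapid
    steps), else 'gradual'.  Labels are invariant to rescaling all counts.
    """
    times = samples.times(table.condition)
    if len(times) < 3:
        raise ValueError("need >= 3 reference times to label intervals")
    totals = []
    for t_from, t_to in zip(times[:-1], times[1:]):
        tot = table.count(float(t_to), 1, "up") + table.count(float(t_from), 1, "down")
        totals.append(tot)
    totals = np.asarray(totals, dtype=float)
    cutoff = float(np.quantile(totals, rapid_quantile))
    labels = np.where(totals > cutoff, "rapid", "gradual")
    return pd.DataFrame(
        {
            "condition": table.condition,
            "t_from": times[:-1],
            "t_to": times[1:],
            "one_hop_total": totals.astype(int),
            "label": labels,
        }
    )
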