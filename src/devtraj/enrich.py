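"""Annotation-term over-representation in DE gene sets.

One-sided hypergeometric test (equivalently Fisher's exact upper tail) per
term: given a universe of U genes of which n carry the term, and a DE set
of N genes with x carrying the term, p = P[X >= x] for X hypergeometric.
No correction across terms by default — the analysis is framed as
hypothesis generation at raw p <= 0.05 — with Benjamini-Hochberg available
behind a flag.  The annotation map is flat: no ontology-graph
decorrelation, and the gene universe is always an explicit input.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

__all__ = ["enrich"]


def enrich(
    de_genes,
    universe,
    annot: AnnotationMap,
    *,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a DE gene set.

    Returns a table sorted by p with columns term_id, overlap, term_size,
    de_size, universe_size, p, (fdr if ``bh_correct``), significant.  A term
    with zero overlap has p = 1.0 exactly.  Raises on an empty universe or
    DE set, or if ``de_genes`` is not contained in ``universe``.
    """
    universe = {str(g) for g in universe}
    de_genes = {str(g) for g in de_genes}
    if not universe:
        raise ValueError("empty gene universe")
    if not de_genes:
        raise ValueError("empty DE gene set")
    stray = de_genes - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]}")
    annot = annot.restricted_to(universe)

    U, N = len(universe), len(de_genes)
    rows = []
    for term in sorted(annot.terms):
        members = annot.genes_for_term(term)
        n = len(members)
        x = len(members & de_genes)
        # upper tail P[X >= x]; sf(x-1) so zero overlap gives exactly 1
        p = float(hypergeom.sf(x - 1, U, n, N))
        rows.append((term, x, n, N, U, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "overlap", "term_size", "de_size", "universe_size", "p"],
    )
    if bh_correct and len(out):
        _, fdr, *_ = multipletests(out["p"], method="fdr_bh")
        out["fdr"] = fdr
        out["significant"] = out["fdr"] <= alpha
    else:
        out["significant"] = out["p"] <= alpha
    return out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
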