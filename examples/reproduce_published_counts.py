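"""Reproduce the published filtering and PCA figures from the deposited data.

The original study deposited read counts for the two developmental time
courses (GEO accession GSE61914: 19 filter time points x 2 replicates and
10 suspension time points x 3 replicates, one sample missing).  This script
cannot download them; place local TSV exports under data/GSE61914/ as

    data/GSE61914/filter_counts.tsv       genes x 38 samples
    data/GSE61914/suspension_counts.tsv   genes x 29 samples
    data/GSE61914/gene_lengths.tsv        gene_id, length_bp

then run it from the repository root.  It checks:

* threshold-30 filtering retains 8,766 (filter) / 8,593 (suspension)
  genes, with 8,040 intersecting;
* per-experiment PCA on the 8,040 intersected genes reports PC1/PC2
  variance fractions 28.6%/19.6% (filter) and 31.2%/17.3% (suspension)
  under one of the probed preprocessing conventions (the original
  convention is not on record, so raw/log RPKM x centered/scaled are all
  tried and the match is reported).
"""

from pathlib import Path

import numpy as np

import devtraj as dt

DATA = Path("data/GSE61914")
PUBLISHED_COUNTS = {"filter": 8766, "suspension": 8593, "intersection": 8040}
PUBLISHED_PCA = {"filter": (28.6, 19.6), "suspension": (31.2, 17.3)}

paths = [DATA / "filter_counts.tsv", DATA / "suspension_counts.tsv",
         DATA / "gene_lengths.tsv"]
missing = [p for p in paths if not p.exists()]
if missing:
    raise SystemExit(
        f"missing input files: {[str(p) for p in missing]}\n"
        "Supply local copies of the deposited count tables (see docstring)."
    )

filt = dt.read_counts(paths[0], paths[2])
susp = dt.read_counts(paths[1], paths[2])

kept_f = dt.filter_low_expression(filt, 30)
kept_s = dt.filter_low_expression(susp, 30)
inter_f, inter_s = dt.intersect_genes(kept_f, kept_s)
print(f"retained genes: filter {kept_f.shape[0]} (published "
      f"{PUBLISHED_COUNTS['filter']}), suspension {kept_s.shape[0]} "
      f"(published {PUBLISHED_COUNTS['suspension']}), intersection "
      f"{inter_f.shape[0]} (published {PUBLISHED_COUNTS['intersection']})")

for name, cm in (("filter", inter_f), ("suspension", inter_s)):
    expr = dt.rpkm(cm)
    print(f"\n{name}: probing PCA preprocessing conventions "
          f"(published PC1/PC2 = {PUBLISHED_PCA[name]})")
    for conv, mat in (("rpkm", expr), ("log2(rpkm+1)", np.log2(expr + 1.0))):
        for scale in (False, True):
            emb = dt.pca_embed(mat, scale=scale)
            v = tuple(round(100 * f, 1) for f in emb.variance_fractions)
            close = all(
                abs(a - b) <= 0.5 for a, b in zip(v, PUBLISHED_PCA[name])
            )
            tag = "  <-- matches published values" if close else ""
            print(f"  {conv:>13s}, scaled={scale!s:5s}: "
                  f"PC1 {v[0]:.1f}% PC2 {v[1]:.1f}%{tag}")
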