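"""RPKM-normalize a simulated course and filter low-expression genes.

Genes with fewer than 30 reads at every time point of an experiment are
dropped per experiment, then the two surviving sets are intersected — the
same pipeline order used for the published 8,766 / 8,593 / 8,040 counts.
"""

import numpy as np

import devtraj as dt

program = dt.random_program(3000, rng=np.random.default_rng(1))
counts, samples, _ = dt.generate(dt.SimConfig(n_genes=3000, seed=1), program)

filt_ids = samples.for_condition("filter")["sample_id"].tolist()
susp_ids = samples.for_condition("suspension")["sample_id"].tolist()

kept_f = dt.filter_low_expression(counts.subset_samples(filt_ids), threshold=30)
kept_s = dt.filter_low_expression(counts.subset_samples(susp_ids), threshold=30)
inter_f, inter_s = dt.intersect_genes(kept_f, kept_s)

expr = dt.rpkm(counts.subset_genes(inter_f.gene_ids))
print(f"genes surviving >=30 reads: {kept_f.shape[0]} (filter), "
      f"{kept_s.shape[0]} (suspension), {inter_f.shape[0]} in both")
print(f"RPKM matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
col = expr.columns[0]
print(f"sample {col}: median RPKM {expr[col].median():.2f}")
# RPKM divides each count by gene length (kb) and library size (millions),
# so values are comparable across genes and samples; the intersected gene
# set is the common currency for all cross-experiment comparisons.
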