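"""Embed a time course as a 2-D trajectory and find its leaps and lulls.

PCA and metric MDS (on 1 - |Spearman| distances) place each sample in a
plane where proximity means transcriptome similarity.  Consecutive
replicate-centroid distances quantify how fast the population transcriptome
moves per step; steps beyond median + 2*MAD are labeled leaps.
"""

import numpy as np

import devtraj as dt

rng = np.random.default_rng(2)
program = dt.random_program(
    2000, t_min=0, t_max=28, stage_boundaries_h=(8.0, 16.0),
    leap_fraction=0.12, leap_log2fc=2.5, drift_rate=0.02, rng=rng,
)
counts, samples, truth = dt.generate(dt.SimConfig(n_genes=2000, seed=2), program)
expr = dt.rpkm(counts)
filt_ids = samples.for_condition("filter")["sample_id"]

emb = dt.pca_embed(expr[filt_ids], samples)
v1, v2 = emb.variance_fractions
print(f"PCA: PC1 {100*v1:.1f}%, PC2 {100*v2:.1f}% of variance")

dist = dt.spearman_distance(expr[filt_ids])
mds = dt.mds_embed(dist, samples)
print(f"MDS: final stress {mds.stress:.4f} after {len(mds.stress_trace)} iterations")

gaps = dt.centroids_and_gaps(emb, samples, "filter")
print(gaps.steps[["t_from", "t_to", "distance", "label"]].to_string(index=False))
print(f"planted boundaries were {truth['stage_boundaries_h']}")
# Leap-labeled steps should bracket the planted boundaries: those are the
# concerted expression shifts separating developmental stages, while lull
# steps are within-stage drift.
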