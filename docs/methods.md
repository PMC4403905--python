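# Methods

`devtraj` analyses bulk RNA-seq time courses of staged development — the
motivating system is *Dictyostelium discoideum* developing on filters
(0–24 h) or as cAMP-pulsed suspension cultures (0–12 h), sampled hourly
and then two-hourly.  The package treats each whole-transcriptome sample
as a point and a time course as a trajectory, and asks where that
trajectory moves smoothly ("lulls") and where it jumps ("leaps").

## Data model

Counts are integer reads per gene per sample with a per-gene mapable
transcript length; samples carry (condition, time in hours, replicate).
Time is a real number, never an index, so irregular sampling is
first-class; downstream "hop" logic that needs discreteness states its
convention explicitly (below).  Missing samples are absent rows, never NA
columns.

## Normalization and filtering

RPKM: `count / (length_kb x total_reads_millions)`.  The per-sample total
is the column sum of the supplied counts — the original run-level mapped
totals are not recoverable downstream of counting, and the difference is a
per-sample constant that cancels in rank-based analyses.  Low-expression
filtering drops genes with < 30 reads in **every** sample of an
experiment, per experiment, and the surviving sets are then intersected
(this order matters and matches the published 8,766 / 8,593 / 8,040
pipeline).  Per-gene standardization (z-score or max-scaling) is available
but defaults to off, because cross-gene amplitude comparisons are part of
the analysis.

## Trajectory embeddings

**PCA** operates on per-gene mean-centered expression without
unit-variance scaling by default (scaling is a flag; the original
convention is unrecorded, so the reproduction probe tries both).  Axis
signs are fixed by orienting the earliest time point non-positive.

**MDS** is metric SMACOF majorization on `1 - |Spearman rho|`
dissimilarities, initialized by classical (Torgerson) scaling.  The start
is deterministic, the Guttman transform guarantees a monotone
non-increasing stress trace, and iteration stops at a relative stress
decrease below 1e-9 (max 500 iterations; non-convergence returns the best
configuration flagged `converged=False`).  Stress is Kruskal stress-1.
The absolute value in the distance means perfectly anti-correlated
profiles are treated as *similar*; this is a property of the chosen
dissimilarity, not a bug, and is exercised in the tests.

**Gaps.** Replicate centroids per (condition, time) turn an embedding into
an ordered trajectory; consecutive centroid distances are the gap profile.
A step is a **leap** when its distance exceeds `median + c * MAD`
(unscaled MAD, `c = 2` by default).  The rule is a robust quantitative
stand-in for what the original analysis read off plots by eye; `c` is
config and recorded in the output.  With equal distances MAD is zero and
the strict inequality labels nothing — uniform motion has no leaps.

**Clustering.** Average-linkage hierarchical clustering of samples on the
same dissimilarity, with ordinary gene-bootstrap support per internal node
(fraction of resampled trees reproducing the node's exact membership).
Multiscale/AU correction is deliberately out of scope.

## Differential expression

Per time-point pair, a per-gene negative-binomial likelihood-ratio test of
equal means (var = mu + phi mu^2), with:

* **size factors** by median-of-ratios (geometric-mean reference),
  because total-count factors convert a block of genuinely shifted genes
  into spurious calls on everything else (composition bias);
* **dispersions** estimated once from the full series, never per pair:
  method-of-moments within time-point groups, then log-space shrinkage
  toward a parametric trend `phi(mu) = a0 + a1/mu` with prior weight
  `residual_df / (residual_df + prior_df)`, `prior_df = 50`.  Two design
  points matter for calibration: the trend is fit on *all* finite moment
  estimates including negative ones (conditioning on positivity inflates
  the trend and makes the test conservative), and the prior is strong
  because per-gene estimates at 2–3 replicates carry so little information
  that lightly-shrunk values make the chi-squared tail anti-conservative
  exactly where BH-FDR operates.  With these choices the measured type-I
  error at nominal 0.05 is ~0.051 and the far tail is within ~1.5x of
  nominal (verified by simulation in the test suite);
* group means fitted by vectorized Newton iteration on log-mean with
  offsets; dispersion below 1e-8 switches to the exact Poisson limit;
* Benjamini–Hochberg adjustment across genes within each comparison
  (default FDR 0.01); directions relative to the later time point; fold
  changes with a 0.5 pseudocount.

The engine is pluggable: `calls_from_table` ingests any externally
computed per-pair table (e.g. an empirical-Bayes posterior pipeline) with
the same columns, and all downstream stages consume only that table.

## k-hop accounting

For each reference time, up-regulated genes are counted looking back
(reference vs 1, 2, 3, 4 hops earlier) and down-regulated genes looking
forward; a gene DE at several hops is assigned only to the smallest
("smallest-delta deduplication"), so bins partition the DE union.  A
**hop** is a step between adjacent *sampled* time points — after the
sampling interval widens to 2 h, one hop spans 2 h of clock time.  This is
the only reading consistent with k = 1–4 windows running through the
two-hourly tail of the series; a `hop_mode='clock'` alternative scans
exact clock-hour offsets and leaves bins empty where no sample exists.
Steps are labeled **rapid** when their 1-hop total strictly exceeds the
0.75 quantile of all 1-hop totals in the condition (config-exposed; the
original figure-level criterion is not stated quantitatively).

## Time prediction

Expression is centered with training-set gene means and projected on the
top-q principal axes of the training samples; ordinary least squares
regresses time on the q scores.  Direct OLS on thousands of genes with
tens of samples is underdetermined, so some reduction is unavoidable;
principal-component regression keeps the model linear in expression and
deterministic.  `q='auto'` maximizes leave-one-timepoint-out rank accuracy
(pooled held-out predictions, smallest q on ties, q <= 10).  Accuracy is
Spearman rank correlation between predicted and true times (average ranks
for replicate ties) — the developmental order, not the clock — and the
mean signed offset (predicted − true) estimates the temporal lag between
conditions.

A practical caveat established during validation: the offset is measured
without bias only where the test samples' developmental states lie inside
the training range.  Testing a model on states it never saw (e.g. the
earliest filter samples against a model trained on a lagged short course)
shrinks extrapolated predictions toward the training mean and biases the
measured lag toward zero.  The lag-recovery check therefore trains on the
long course and tests on the lagged short course — mirroring the
asymmetric real design, where the 24 h filter course spans every state the
12 h suspension course reaches.

## Enrichment

One-sided hypergeometric upper-tail test per annotation term against an
explicit, caller-supplied gene universe (which universe is appropriate —
all genes, expressed genes, or the cross-experiment intersection — is a
scientific choice the package refuses to default).  Raw p at alpha 0.05 by
default, matching the hypothesis-generation framing; BH correction behind
a flag.  The map is flat: no ontology graph, no term decorrelation.

## Synthetic data

The generator emulates the motivating study design: condition 1 sampled
hourly 0–12 h then two-hourly to 24 h (19 points, 2 replicates),
condition 2 hourly 0–6 h then two-hourly to 12 h (10 points, 3
replicates) with the (12 h, replicate 3) sample missing — 67 samples over
12,000 genes by default.  Gene programs are log-normal baselines with
per-gene exponential drift (bounded by `drift_rate`, default fractions of
a percent to a few percent per hour) and a subset of **leap genes** that
jump by ±`leap_log2fc` log2 units at designated stage boundaries.  Counts
are NB(mean, dispersion) with mean = library_factor x program_mean x
length_kb, log-normal library factors (sigma 0.25), gene lengths uniform
in [500, 5000] bp, dispersion 0.05 (dispersion 0 gives the exact Poisson
limit).  A `condition2_lag_h` knob evaluates condition 2's program at
t + lag (truncated to the program domain), emulating the ~4 h lead of
cAMP-pulsed suspension cells.  The original work gives no quantitative
leap amplitude; defaults (10–15% of genes, 2–2.5 log2 units) are chosen
for detectability, not biological fidelity.

What the generator does **not** emulate: mapping bias, 3' coverage
effects, unmeasured non-polyadenylated/mitochondrial transcripts,
gene–gene correlation beyond the shared stage structure, or
replicate-level batch effects.  A green simulation test therefore
establishes internal consistency of the method chain, not robustness to
those artifacts.

## Numerical choices and degenerate inputs

* Zero-variance genes: z-scored to all-zeros with a log warning;
  constant sample profiles are an error for Spearman distances (rho
  undefined).
* All-zero genes: p = 1, never DE; zero-count groups fit mean 0 exactly.
* Newton fits clip steps to ±5 on the log scale and stop at 1e-12; ties
  in ranks use average ranks throughout.
* Equal distances / uniform counts: strict inequalities in the leap and
  rapid rules label nothing.
* Determinism: every stochastic component takes a seed or Generator; the
  MDS start is deterministic by construction.

## Known limitations

* RPKM denominators differ from the original run-level mapped totals by a
  per-sample constant; printed RPKM values are comparable within this
  pipeline but not bit-identical to the original study's.
* The NB-LRT engine is a substitute for the original empirical-Bayes
  engine; per-pair DE gene counts are therefore not comparable to the
  published supplementary tables (the shim exists to ingest them).
* Bootstrap support values are ordinary proportions and read lower than
  AU p-values for the same tree.
* The time model is linear; strongly stage-like (piecewise) dynamics are
  handled only insofar as they correlate with the principal axes.
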