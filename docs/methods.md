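# Methods

`sgccanet` integrates three sample-aligned omic blocks — CpG methylation,
transcript expression, miRNA expression — by sparse generalized canonical
correlation analysis (SGCCA), stabilises the selected feature set by
subsample refitting, interprets it through gene-set enrichment, and
reconstructs mutual-information (MI) networks whose edge thresholds are
calibrated on known regulatory interactions. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not show.

## Preprocessing

CpG methylation enters as beta values in [0, 1]. Features missing in
strictly more than `max_missing_fraction` of samples (default 0.25) are
dropped; the boundary is exclusive, so a feature missing in exactly 25% of
samples survives. Remaining gaps are imputed from the `k = 10` nearest
*sample* neighbours under plain Euclidean distance over co-observed
features; only samples observing the feature are candidates, and all
imputations read the original observed entries (no sequential fill-in).
Imputed betas are mapped to M-values, `M = log2(b / (1 - b))`, after
clamping into `[eps, 1 - eps]` with `eps = 1e-6`; the clamp only matters for
betas at exactly 0 or 1.

Each block is then divided by the square root of the largest eigenvalue of
its column-centered sample covariance (the `1/(n-1)` convention), so the
leading eigenvalue of every block becomes 1. After this scaling a block's
influence on the joint fit depends on how its variance is distributed across
directions, not on its units or dimensionality.

## The sparse multi-block model

With blocks `X_1..X_J` and a symmetric nonnegative design matrix `C`
(zero diagonal; default fully connected, `c_jk = 1`), the centroid-scheme
objective is

    maximize  sum_{j<k} c_jk |cov(X_j a_j, X_k a_k)|
    s.t.      ||a_j||_2 = 1,   ||a_j||_1 <= s_j * sqrt(p_j)

The absolute value admits negatively correlated blocks. The per-block
sparsity `s_j` in `(1/sqrt(p_j), 1]` sets an l1 budget: separate budgets per
omic avoid over-penalising a block whose effects are smaller than another's.
Smaller `s_j` selects fewer features; the constraint's proximal map
(soft-threshold, renormalise, bisect on the threshold) produces exact zeros.

The solver is block-coordinate ascent. Updating `a_j` maximises `v'a` over
the sphere/l1-ball intersection, where `v = X_j' z_j` and
`z_j = sum_k c_jk sign(cov(y_j, y_k)) y_k` linearises the absolute values at
the current signs; every such step is a minorise-maximise move, so the
objective trace is non-decreasing (asserted in the tests). Convergence is
declared when the objective gain falls below `tol = 1e-8` (relative), with
`max_iter = 1000`; non-convergence flags the model instead of raising.

**Multi-start.** The `|cov|` terms make the objective multimodal: on random
tiny instances a single ascent run can stall several percent below the
global optimum. Each component therefore runs `n_starts = 16` deterministic
starts — the dominant-right-singular-vector initialisation (projected onto
the constraint set), its relative sign flips across blocks, and fixed-seed
random unit vectors — keeping the run with the best final objective. The
whole procedure remains bit-reproducible. The test suite checks the fitted
objective against a dense sphere-grid-search oracle on tiny instances.

Further components come from deflating each block by its own component
score, `X <- X - y (y'X)/(y'y)`. Extraction stops early when every deflated
block is numerically zero or the objective falls below `tol`; the pipeline
caps the requested `ncomp` (default `n - 1`) at the blocks' rank, with a log
entry. Per block and component, AVE — here the *variance-weighted* mean of
squared feature-score correlations, a choice the interface documents — is
reported on the original (pre-deflation) centered block.

## Sparsity tuning and stability selection

`tune_sparsity` scans the grid `0.01..0.09 (step 0.01), 0.1..0.9 (step 0.1)`
one omic at a time, holding the other omics at a reference value of 0.1
(clamped up to `1/sqrt(p)` when 0.1 is infeasible for a small block). For
each candidate it runs a one-component fit on `reps = 10` class-balanced
subsets (`per_group = 10` samples per group) and records the tuned block's
AVE and selected-feature count. The same balanced draws are reused for
every grid value (common random numbers): AVE differences along the grid are
then paired comparisons, which matters because the AVE profile is nearly
flat once the signal-carrying features are in. The chosen value follows a
one-standard-error rule — among values whose mean AVE is within one SE of
the best, the one selecting fewest features (ties to the smaller value).

`stability_select` refits the final model `n_runs = 100` times (50 in the
desk-scale benchmark) on `floor(0.5 n)` samples drawn without replacement;
a feature counts as selected in a run if any component gives it a non-zero
loading, and features selected in at least `keep_threshold = 0.7` of runs
are kept. Draws are made over the sorted sample ids, so frequencies are
invariant to the row order of the inputs. Per-run seeds derive from the
master seed through a counter.

## Enrichment analytics

Features map to genes through the annotation table: transcripts one-to-one,
miRNAs by direct name (`hsa-mir-34b -> MIR34B`), CpG probes to *every*
overlapping gene — an amplification of CpG representation that the output
consumer must keep in mind. Over-representation uses the hypergeometric
upper tail `P(X >= k)` against a universe defaulting to all genes reachable
from the annotation (configurable), with Benjamini-Hochberg FDR across terms
and significance at FDR < 0.01. The pipeline runs one ORA per component on
the stability-kept co-selected features and aggregates per term, recording
the set of components in which each term is significant.

Preranked GSEA ranks genes by the transcript-block log fold change (group
mean minus reference mean on the log scale, Welch test for the node
attributes) and uses the weighted running sum: hits step `+|s|/NR`, misses
step `-1/(n - n_hit)`; ES is the maximum deviation. The null comes from
`n_perm = 1000` gene-label permutations; `NES = ES / mean(|null ES| of the
matching sign)` and the p-value is the same-sign permutation tail with the
`(1 + x)/(1 + n)` correction. Every term is reported regardless of p.

Cross-group structure: UpSet-style exact-intersection counts; the Jaccard
index of the hit-gene sets behind any term enriched in two groups; Fisher's
exact test (two-sided, a choice — sidedness is not dictated by the model)
on class membership of exclusively enriched terms, Bonferroni-adjusted over
all (class, group) pairs at 0.05; and function clustering by the Jaccard
overlap of contributing-component sets at `tau = 1.0` (exact component-set
sharing) by default, returned as connected components with singletons also
listed as unclustered.

## MI networks calibrated on priors

One MI estimator is used everywhere: equal-frequency binning with
`nbins = ceil(n^(1/3))`, stable tie-breaking by sort order, plug-in entropy,
natural log. Using a single estimator for both the all-pairs scores and the
prior calibration removes a cross-estimator bias that would otherwise enter
the thresholds — a deliberate unification, since nothing forces the two
steps to share an estimator. Only the four admissible edge types are ever
scored: CpG-transcript, CpG-miRNA, TF-transcript-transcript,
miRNA-transcript; CpG-CpG and non-TF transcript pairs are excluded.

Thresholds: per edge type, the *median* MI of the prior regulatory edges
present in the data (median, not mean, so a single outlying prior cannot
dominate; the median of an even-length list is the mean of the central
pair). Two-sample Kolmogorov-Smirnov tests compare the all-pairs MI
distributions between edge types at `alpha = 0.05`; if no pair differs
significantly the minimum per-type median becomes one unified threshold,
otherwise each type keeps its own. Edges are retained when `MI >=`
threshold — a closed inequality, so ties survive. An optional
data-processing-inequality pass removes, in every triangle, the weakest edge
when its MI is below `(1 - tolerance)` times the smaller of the other two,
with all marks taken on the original weights before any removal.

Node analytics: degree on the full network; betweenness from unit-length
shortest paths, normalised by `(n-1)(n-2)/2`; functional subgraphs keep the
connected components containing at least one feature annotated to the
function under study, optionally restricted to the functional features and
their first neighbours (vertex-induced).

## The synthetic benchmark

The generator plants the structure the method is built to find: latent
factor scores `z_h` per sample (group-specific means, spacing 1.0, unit
noise) drive `x = beta z_h + eps` in 10/10/5 features of the three blocks
(`|beta| = signal_sd = 3`, `eps ~ N(0, noise_sd = 1)`); all other features
are pure noise. The CpG block passes through a logistic squash to beta
values (making the M-value transform its exact linear inverse) and receives
5% missing entries. The annotation links planted CpGs to planted
transcripts' genes of the same factor, so prior edges between planted
features are annotation-consistent; priors contain equal numbers of true
(planted-planted) and decoy (noise-noise) edges per type; one gene set
collects the planted genes, one only-noise genes, the rest are random.
Defaults: 2 groups x 50 samples, blocks 200/150/50 — the problem sizes used
throughout the tests and the acceptance script, with n = 200 for the MI
calibration checks where the estimator needs more samples.

Recovery experiments need a sparsity value; the package's rule, fixed up
front, is an l1 budget of `0.9 sqrt(k)` for a planted group of size k — 10%
inside the `l1/l2` norm ratio of the ideal uniform k-sparse loading, the
margin absorbing estimation-noise leakage into off-support coordinates. The
behaviour is a broad plateau in this margin, not a tuned point.

What passing does *not* show: the generator draws Gaussian factors with
linear effects and independent noise — no read-count mean-variance
coupling, GC/length bias, batch structure, correlated noise, or realistic
annotation ambiguity. Recovery here demonstrates correctness of the
machinery under its own model assumptions, not performance on platform data,
whose acquisition-side corrections are explicitly out of scope.

## Degenerate inputs and numerical edges

Zero-variance blocks cannot be eigenvalue-scaled (error); zero-variance
features are excluded from AVE; a zero score vector stops deflation for that
block; `project_l1_sphere` falls back to a signed one-hot when soft
thresholding cannot meet the budget (exact ties at the maximum); constant
vectors discretise into a single bin with a warning; Welch tests on
degenerate variances report p = 1 with a flag; the Jaccard index of two
empty sets is an error rather than a convention.

## Known limitations

- Only the centroid scheme is implemented (no Horst/factorial variants, no
  orthogonality constraints across components beyond deflation).
- Tuning scans one omic at a time against fixed references; interactions
  between the three sparsity values are not explored.
- The binned plug-in MI estimator is biased upward at small n; thresholds
  calibrated and applied with the same estimator on the same samples cancel
  most of this in comparisons, but absolute MI values should not be read as
  unbiased dependence measures.
- CpG-CpG dependence is deliberately never scored, so methylation-internal
  structure is invisible to the networks.
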