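# Methods

This note documents the models and algorithms implemented in cytopipe,
the defaults and the reasoning behind them, what the synthetic
benchmark does and does not emulate, and the numerical choices that
affect results.

## Data model

A *Sample* holds an events matrix (rows = cells, columns = channels),
channel metadata keyed by the FCS `$PnN` short name, the raw TEXT-segment
keywords, named per-event tag vectors, and an append-only provenance
log.  Events are stored **transformed in place**: each stage overwrites
the matrix and records its parameters in provenance, so the original
scale is recoverable by applying the recorded inverse transforms rather
than by caching raw copies.  All selection operations (gating,
downsampling, splitting, clustering) are non-destructive tags; no stage
ever deletes an event.

Channel identity across samples is matched by `$PnN`; user-facing
labels are free to change (`subset_rename`) and are exported as `$PnS`,
keeping `$PnN` stable — so files re-opened in other software still key
on the acquisition names.

Checkpoints are a single zip container of `.npy` arrays plus a JSON
manifest with a format/version field; the round trip is bit-exact,
including tags and provenance.

## Transformations

Cytometry intensities span decades and carry meaningful values near and
below zero, so display transforms must be linear around zero and
logarithmic at high signal.

* **arcsinh**: `y = asinh(a + b·x) + c`.
* **biexponential**: `y` solves
  `B(y) = a·e^{b(y−w)} − c·e^{−d(y−w)} + f = x`, by bisection-guarded
  Newton iteration to 1e-8 absolute tolerance (the defaults
  a = c = 0.5, b = d = 1, f = w = 0 make it exactly `asinh`, which the
  tests exploit as a closed-form oracle).
* **logicle** (Parks–Roederer–Moore family, parameters *t* top of
  scale, *m* total decades, *w* linearization width in decades, *a*
  extra negative decades): the closed form is the scale→data function
  `S(u) = α·e^{bu} − γ·e^{−du} + φ` with coefficients fixed by
  `S(1) = t`, `S(x₁) = 0` at the center of the linear region, and the
  width condition `2(ln d − ln b) + w_n(b + d) = 0`; the forward
  transform inverts S numerically (bisection-guarded Newton).  Output
  is in decades on `[0, m + a]`, so t maps to m + a and transformed
  values are comparable across channels before rescaling.

Values below the logicle domain floor `S(0)` are clamped to the floor
and counted.  All three transforms are strictly increasing on their
domain, verified by dense grid scan; round trips are exact to better
than 1e-10 relative error inside the domain.

The logicle estimator follows the de-facto standard rule: t from
`$PnR` (or the observed maximum), m = 4.5, a = 0, and
`w = max(0.1, (m − log10(t/|r|))/2)` with r the 5th percentile of the
channel's negative events; channels without negatives get w = 1.0.  The
result is a starting point meant to be reviewed, not an oracle.

## Compensation

Spillover is linear in signal: `observed = true · S` with `S[i][j]` the
fraction of channel-i signal read by detector j (unit diagonal).
Compensation right-multiplies by `S⁻¹`.  Because the algebra is only
valid on the linear scale, compensating an already-transformed dataset
inverse-transforms the covered channels, unmixes, and re-transforms —
callers pass the transform specs they applied.  Matrices come from each
sample's `$SPILLOVER`/`SPILL` keyword (per-sample mode) or one shared
matrix file; mass-cytometry datasets simply skip the stage.
Compensation is not idempotent, so a provenance check warns when it is
applied twice.

## Landmark normalization

Batch effects shift a channel's density peaks; the biology is in the
peaks' *relative* structure.  For each (sample, channel):

1. Gaussian KDE with Silverman's bandwidth on a 512-point grid over the
   channel range; local maxima with prominence ≥ 5% of the global
   density maximum are candidates; the L most prominent (by density)
   are the sample's landmarks, sorted by position.  Samples yielding
   fewer than L peaks are flagged and excluded from consensus; if more
   than half the samples flag, the channel demands manual overrides
   (supplied as a TSV of sample, channel, rank, position — the
   scriptable replacement for interactive peak editing).
2. Landmarks are matched across samples **by rank** (the low peak to
   the low peaks, the high to the high), and the target for rank r is
   the per-rank median across samples — robust to one aberrant sample.
3. Each sample is warped by the continuous piecewise-linear map sending
   its landmarks to the targets, with slope-1 (pure shift)
   extrapolation beyond the outermost landmarks.  L = 1 degenerates to
   a global shift.  The map is strictly increasing whenever landmarks
   and targets are each strictly increasing, so event rank within a
   sample is preserved; out-of-order configurations raise rather than
   silently folding the scale.

This is landmark registration in the gaussNorm lineage, but with a
piecewise-linear warp instead of Gaussian-weighted shifts: it is
monotone by construction and its behavior away from the landmarks is
explicit.  The measure of success is the alignment itself — on
two-batch synthetic data with a 0.4-unit shift, the cross-sample SD of
every aligned peak rank falls from ≈0.2 to below 0.01.

Control samples shared across batches need no special handling: they
participate in the consensus like any other sample.

## Gating

Four shapes (rectangle, polygon, quadrant, 1D interval) with numeric
geometry in a declarative YAML file; per-sample overrides replace the
geometry wholesale.  Gates form a tree: each gate's membership tag is
ANDed with its parent's.  Boundary convention: closed on lower/left,
open on upper/right, so the four quadrant tags partition the parent
population exactly; polygon boundary points count as inside (implemented
with matplotlib's Path with a ± epsilon radius, which is orientation-
robust, and verified against a brute-force ray-casting oracle).

## Downsampling, rescaling, splitting

The balanced downsample quota `Q = min_g(m_g · min_{s∈g} n_s)` is the
largest value satisfying both equality constraints (equal group
contributions; equal sample contributions within a group) without
replacement; each sample of group g contributes `⌊Q/m_g⌋` cells, drawn
uniformly without replacement.  Draws use one substream per sample
(seed combined with a hash of the sample ID), so adding or reordering
samples never perturbs the other samples' draws.

Rescaling maps each channel through clipped percentile min-max
(defaults 0.1/99.9) to [0, 1], pooled over **all** events of all
samples regardless of the downsample tag — percentile bounds are
recorded in provenance.  Bounded output stops high-magnitude channels
from dominating Euclidean distances downstream; the percentile clip
makes the bounds robust to outliers.  z-scoring was rejected because it
leaves the output unbounded and sensitive to heavy tails.

Splitting assigns `⌊fraction·n⌋` of each sample's eligible cells
(downsampled-tagged if present, else all) to half A and the rest to B,
so both halves contain every sample — per-sample splitting already
preserves group composition, and no extra stratification is applied.

## Guided semi-supervised clustering

Operating on the downsampled, rescaled channels:

1. **Training**: a uniform random `training_fraction` (default 0.1) of
   tagged cells is clustered agglomeratively — Ward linkage on
   Euclidean distance, the standard choice for compact elliptical
   phenotype clusters — and the dendrogram is cut at `K_init`
   (default 100).  Deliberate over-segmentation: K_init only needs to
   exceed the true population count; the collapse stage removes the
   excess.
2. **Propagation**: every remaining tagged cell takes the majority
   label of its `k_nn` (default 11, odd to reduce ties) nearest
   training cells; vote ties resolve to the single nearest neighbor's
   label.  Neighbor search uses a tree index but is exactly equivalent
   to brute force, which the tests assert.
3. **Binarization**: each cluster becomes a bit vector over the
   clustering channels — bit = 1 iff strictly more than half its cells
   exceed the channel's positivity threshold (a fraction of exactly
   one half stays negative).  Thresholds are normally set by eye;
   `estimate_thresholds` automates the default as the KDE
   minimum-density valley between the two main modes (pooled over all
   samples), falling back to the pooled median for unimodal channels,
   and any threshold can be overridden.
4. **Collapse**: clusters with identical bit vectors merge first; then,
   while more than `K_max` (default 40) remain, the pair at smallest
   Hamming distance between bit vectors merges.  Ties break to the
   pair containing the smallest cluster (merging small fragments
   first), then to lowest IDs — fully deterministic.  The merged
   phenotype is recomputed from the pooled member events
   (size-weighted positivity fractions), so chains of merges cannot
   drift from what the pooled cells actually express.  Final clusters
   are renumbered 1..K_final by decreasing size.  Collapsing is
   idempotent and never increases the cluster count.

UMAP (n_neighbors = 15, min_dist = 0.1, Euclidean) embeds the same
tagged cells for visualization; a fixed random_state forces
single-threaded layout, making coordinates reproducible.  The embedding
is cosmetic — clustering never uses it.

## Reporting

Phenotype table: per-cluster per-channel median rescaled intensity.
Abundance table: percent of each sample's clustered cells per final
cluster (rows sum to 100; absent clusters zero-filled).  Group
comparisons use the two-sided Wilcoxon rank-sum test (two groups) or
Kruskal–Wallis (more), with Benjamini–Hochberg adjustment across
clusters — the field-standard nonparametric treatment of cell
frequencies, which are bounded, skewed and small-n.  The sample-level
UMAP embeds samples in abundance space; a sample is flagged an outlier
when its nearest-neighbor distance in that space exceeds the median +
3·MAD.  Outliers are only ever flagged, never removed.

ROC analysis accepts any per-sample real feature (a cluster abundance,
a manually computed score), assumes higher values indicate the positive
group, sweeps every distinct value as a cutoff, and reports AUC via the
rank (Mann–Whitney) formulation — identical to the trapezoidal area on
tie-free data and well-defined under ties — plus the Youden cutoff
(maximizing sensitivity + specificity − 1, lower cutoff on ties).

## The synthetic benchmark

The generator draws each sample from a Gaussian mixture over the
(transformed-scale) marker space.  The standard design: 6 channels,
8 populations with distinct binary marker patterns (negative mode at
1.0, positive at 3.0, σ = 0.15 — comfortably separated but overlapping
in any single channel's tails), 2 groups × 4 samples, 10⁴ events per
sample, an additive 0.4-unit batch shift on two channels for the second
half of each group, and one population whose mixture weight carries the
group effect (30% vs 5%).  A linear-scale mode maps centers through
`sinh` and mixes channels through a known spillover matrix to exercise
transformation and compensation with ground truth.  Per-event truth
labels live in side tables the pipeline never reads.

What it emulates: multimodal marker distributions, additive batch
shifts on the transformed scale, group-differential population
abundances, spillover mixing, realistic FCS files.  What it does not:
debris and doublets, acquisition-time drift within a sample,
non-additive or nonlinear batch distortions, heavy-tailed or skewed
population shapes, rare populations below ~1%, and spectral overlap
beyond a linear matrix.  Passing the benchmark therefore demonstrates
algorithmic correctness under the stated model, not robustness to every
artifact of real acquisitions — the interfaces for handling those
(manual peak overrides, per-sample gates, threshold overrides) are the
tested mitigation path.

Problem sizes in the test suite and reproduction script are scaled to
desk hardware: the end-to-end clustering benchmark runs 2 500 events ×
8 samples (2×10⁴ clustered cells), compensation recovery 10⁵ events,
ROC 5 000 per class; the statistics benchmark uses 10 samples per group
at 10³ events.  All stochastic steps derive from a single seed.

## Numerical choices and degenerate inputs

* Root finding (biexponential, logicle) is bisection-guarded Newton:
  monotone convergence, no divergence on flat slopes; tolerances 1e-8
  (biexponential contract) and ~1e-14 (logicle internal).
* KDE bandwidth is Silverman's rule; the 5% prominence floor suppresses
  ripple peaks.  Both are arguments, not constants.
* A constant channel cannot be rescaled (raises rather than dividing by
  zero); an empty gate parent reports 0% with a flag; an empty cluster
  is skipped with a warning; Kruskal–Wallis on all-identical values
  reports p = 1.
* FCS writing emits exactly one dialect (3.1, float32, little-endian,
  single data segment); reading validates `$TOT` against the decodable
  row count and names both numbers in the error.
* Integer FCS data are masked to the power-of-two range covering
  `$PnR`, per the standard's masking rule.

## Known limitations

* FCS 2.0 and vendor containers are not read; spectral unmixing and
  autofluorescence subtraction are out of scope.
* The hierarchical stage clusters rescaled intensities; markers outside
  the rescaled channel set never influence cluster assignment.
* gaussNorm's per-event Gaussian-weighted adjustment is not
  reproduced; samples whose peak count disagrees with the channel's
  expected L need manual overrides rather than partial matching.
* FlowSOM/PhenoGraph-style alternative clusterers are not implemented;
  the ARI utilities used in testing can compare external labelings if
  needed.
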