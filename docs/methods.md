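# Methods

## Model overview

The package classifies subjects of an MRI cohort as ASD or typical
control with a transductive population graph: structural (T1-weighted)
image similarity defines *which subjects are connected*, and functional
(resting-state) summary statistics define *what each subject looks
like* to the classifier.  The assumption behind this split is that
anatomical similarity groups subjects into homogeneous neighbourhoods
within which functional evidence can be pooled by graph convolution.

## Resting-state summary derivatives

Each derivative collapses the time axis of a 4D run to one 3D map.
Conventions that matter:

* **Mask.**  Default brain mask = voxels with nonzero temporal
  variance; an explicit mask overrides.  Correlations of any pair
  involving a constant series are defined as 0, which keeps maps finite
  and implicitly masks degenerate voxels.
* **ReHo** is Kendall's coefficient of concordance over the voxel plus
  its in-mask neighbours (6, 18 or 26-connectivity, default 26), with
  mid-rank ties and the standard tie-correction term in the
  denominator.  Values are clipped to [0, 1].
* **ALFF / fALFF.**  Per voxel: linear detrend (optional, default on),
  unwindowed DFT, amplitude `2|X_k|/n` per bin.  ALFF is the mean
  amplitude over bins in the low band; fALFF is the summed band
  amplitude over the summed full-band (0–0.25 Hz) amplitude, 0 where
  the denominator vanishes.  Voxels with exactly constant series are
  set to 0 regardless of floating-point detrend residue.  The low band
  defaults to the standard 0.01–0.08 Hz; a band that contains no DFT
  bin for the given run length and TR raises a configuration error
  naming the resolvable range.  Note that detrending a finite sinusoid
  sample leaks a small broadband component, so fALFF of a noise-free
  bin-aligned tone is exactly 1 only with detrending off.
* **Degree / eigenvector centrality** operate on the all-pairs Pearson
  matrix of in-mask voxels at threshold r ≥ 0.25 (configurable).
  Eigenvector centrality makes the matrix nonnegative via the
  (1 + r)/2 rescale (binarized variant: 0/1 entries, diagonal
  included), then power-iterates from the uniform vector to the
  unit-norm leading eigenvector (tol 1e−10, max 1000 iterations).
* **LFCD** grows a face-adjacent (6-connectivity) cluster from each
  seed, admitting neighbours whose correlation *with the seed* meets
  the threshold; the map holds the cluster size including the seed.
* **VMHC** correlates each voxel with its mirror across the first array
  axis (`i ↔ Nx−1−i`; odd first axes have a self-mirroring central
  plane).  Out-of-mask partners give 0.
* **Dual regression** is two-stage ordinary least squares: image-on-
  templates per timepoint, then series-on-timecourses per voxel.
  Rank-deficient designs raise an error naming the stage.

Channel order of the full stack is fixed: reho, alff, falff, dc_bin,
dc_weighted, ec_bin, ec_weighted, lfcd, vmhc, then one dual-regression
channel per template — 19 with the default 10 templates.

## Radiomics

The level-1 wavelet decomposition is **undecimated** (stationary): the
8-tap Daubechies (db4) low/high-pass pair is applied along each axis in
all 2³ combinations without downsampling, so every sub-band shares the
input grid and the atlas mask applies unchanged — this avoids the
mask-resampling ambiguity a decimated transform would introduce.
Filters are scaled by 1/√2 per axis so that, for an orthonormal family
with periodic boundaries, the eight sub-band energies sum exactly to
the input energy (verified by a Parseval test).  Boundary handling
defaults to half-sample symmetric reflection.

Per region and sub-band: the 19 standard first-order statistics
(population moments; entropy/uniformity from a 32-bin min–max
histogram; a constant region has entropy 0 and uniformity 1) and the 22
standard grey-level co-occurrence features.  GLCM discretization is
fixed-bin-count (32 levels) within the region's min–max range, making
texture invariant to global intensity shifts; co-occurrences are
accumulated symmetrically per offset over the 13 unique distance-1
directions, normalised per offset, and features averaged across offsets
with at least one valid in-region pair.  Degenerate matrices define
correlation = 1 and the information measures = 0.  This yields
(19+22) × 8 = 328 features per region and 48,544 per subject at 148
regions.

## Feature selection and embedding

The Fisher score uses class-size-weighted population variances; a
feature whose pooled within-class variance is numerically zero (below
the floating-point summation noise floor for its magnitude) scores 0
rather than exploding.  Ranking ties break toward the lower feature
index so orderings are reproducible.

The stacked autoencoder min–max scales inputs to [0, 1] per feature,
pretrains each of the 4 levels greedily as a one-hidden-layer sigmoid
autoencoder, then fine-tunes the full encoder/decoder stack end to end
under mean squared error (Adam, lr 1e−3, 200+200 epochs by default,
Glorot-uniform init, seeded).  Sigmoid output keeps the embedding in
[0, 1], which the downstream similarity requires to be nonnegative.
Hidden sizes default to the halving ladder 2000→1024→512→256→150 and
are configurable.  Fisher ranking and SAE fitting use training-split
subjects only; all subjects are then encoded — the non-leaking choice.

## Population graph

Similarity is the improved sqrt-cosine form
Σ√(x_i y_i) / (√Σx_i · √Σy_i), which is the Hellinger-affinity analogue
for nonnegative vectors: 1 for identical rows, 0 for disjoint support.
A `literal_form` flag evaluates the plain-product variant for
comparison.  The edge threshold τ is the minimum over rows of the
largest off-diagonal similarity; ties at exactly τ are kept (≥), which
together guarantee minimum degree 1.  Edges are unweighted after
thresholding, matching a propagation rule that uses A and A+I without
weights; the similarity matrix is retained on the graph object for
experimentation.

## Networks and training

Both networks are NumPy with hand-written backpropagation and seeded
Adam, so single-threaded runs are bit-reproducible.

* **3D CNN.**  Blocks are conv(3³, same padding) → ReLU → batch norm →
  max-pool(2³, valid; odd trailing voxels dropped).  The first block
  has 16 filters (chosen so the doubling sequence 32→256 applies to the
  four repeated blocks exactly), then global average pooling, a
  1024-unit ReLU dense layer, dropout 0.5 and a softmax pair.  Node
  features are the post-ReLU dense activations with dropout inactive.
  Training is full-batch cross-entropy; the supervised classification
  pretext is assumed for feature learning.
* **GCN.**  Propagation is H ← ReLU(D̄^{-1/2}(A+I)D̄^{-1/2} H W) without
  biases, two 16-unit hidden layers with input dropouts 0.005 and 0.4,
  a linear output layer and row-wise softmax.  Full-batch Adam
  (lr 0.01, weight decay 5e−4, 200 epochs), Glorot-uniform init.
  Argmax ties break toward the lower class index.

## Synthetic data

The generator emulates the study conditions rather than scanner
physics: a 61×73×61 default grid with TR 2 s, a mirrored 74-per-
hemisphere parcellation built by recursive box bisection (regions are
contiguous boxes; the right hemisphere mirrors the left across the
first axis), disjoint unit-norm template bumps, and rs-fMRI volumes
with one of five planted structures (mirror symmetry, locally
homogeneous blocks, template mixtures, white noise, bin-aligned pure
tones).  Cohorts plant a class effect as a mean-intensity shift of
designated regions in the structural volume (default: the first 10
region ids, shift `effect_size` in class 1) plus an optional functional
effect (class-1 subjects carry a stronger low-frequency oscillation on
the first template's support).  It does **not** emulate motion, site
effects, physiological noise or anatomical variability, so passing
tests demonstrate correctness of the computations and recoverability of
planted signal — not clinical performance on real cohorts.

Tests and the orchestration default run at miniature problem sizes
chosen to exercise every code path cheaply: 12×14×12 grids, 60
timepoints, 8 regions, 4 templates, 40 subjects with a stratified 80/20
split, selection k = 256, embedding 16, CNN dense width 32.  The
full-scale widths (2000/150/1024) are the component defaults and are
exercised directly in the dimensional-contract checks.

## Stage coupling: what the ablation shows

Because the class effect is planted in the structural features that
build the edges, the thresholded similarity graph is itself
class-informative — at strong effect it splits into two near-disjoint
communities.  A GCN propagates label information through such a graph
regardless of node features: replacing the CNN features with random
vectors leaves test accuracy essentially unchanged (measured
100/100/87.5% across seeds at the default conditions).  Conversely, at
weak structural effect the graph is noisy and, since every layer
multiplies by the normalised adjacency, three propagation hops erase
even a 10-σ node-feature separation — full and feature-randomized runs
then coincide at the graph's own accuracy.  Node features therefore
matter only in the intermediate regime where neighbourhoods are mostly
but not perfectly assortative.  A features-only ablation on this
design cannot reach chance level while the full pipeline stays above
0.9, and the package documents this measured behaviour rather than the
idealised expectation.

## Numerical choices

* Correlation with constant series = 0; eigenvector centrality restarts
  are unnecessary since the rescaled matrix is nonnegative.
* Fisher zero-denominator floor: variances below
  `n·(eps·n·max|x|)²` count as zero.
* Power iteration: tol 1e−10, max 1000 iterations, uniform start.
* Batch norm: eps 1e−5, running-stat momentum 0.1; inference uses
  running statistics.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-subject generators are derived from
  the cohort seed so cohorts are reproducible element-wise.

## Known limitations

* Voxelwise correlation matrices are dense (O(V²)); the summary
  derivatives are intended for masked or miniature grids, not
  whole-brain 2-mm data.
* The CNN and SAE are CPU NumPy implementations: faithful and
  reproducible, but not performant at full 61×73×61×19 training scale.
* The atlas generator produces box-shaped regions; it emulates region
  count, contiguity and mirror symmetry, not cortical geometry.
* Semi-supervised evaluation is transductive (test nodes participate
  in propagation), matching the population-graph setting.
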