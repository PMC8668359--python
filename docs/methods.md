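# Methods

## Pipeline model

The toolkit implements a five-stage classification pipeline for
multiclass dermoscopy images: geometric class-balancing augmentation,
deep-feature extraction at a global average pooling (GAP) layer,
serial feature fusion with a standard-error-of-the-mean (SEM) keep rule,
skewness-screened SVR-validated feature selection, and a multi-classifier
evaluation harness. Each stage is a pure function of its inputs and a
seed; the pipeline orchestrator splits a global seed into per-stage
sub-seeds with `numpy.random.SeedSequence`, so a run is reproducible
hash-for-hash.

## Augmentation and balancing

Three rigid operators act on rasters as index remaps: up/down flip
(row i → m+1−i), left/right flip (column j → n+1−j) and a 90° rotation
(transpose plus one flip). They preserve the pixel multiset per channel
and generate a dihedral group: both flips are involutions and the
rotation has order four. The rotation's direction is not fixed by the
angle alone; counter-clockwise is the default (`direction="cw"`
available).

Balancing brings every class to `target_per_class`. Deficit classes
receive operation chains in a fixed schedule — every original gets the
three single operators first (rot90, lr, ud), then the nine length-2
compositions, then length-3, and so on — so that a class with few
originals can be expanded far beyond the 7 distinct images the operator
group yields per source (chains are distinct as sequences even when two
compositions coincide pixel-wise, e.g. lr∘ud = ud∘lr; the plan invariant
is "no repeated chain per source"). The final partial round draws its
sources by a seeded shuffle. Surplus classes are downsampled by a seeded
uniform choice, which is what forces the largest published class (6705)
down to 6000 and makes the balanced seven-class total exactly 42,000.
Images are not resized at this stage; resizing belongs to the backbone.

## Feature extraction

The extraction contract is: one row per input image, in input order,
tapped at the GAP layer. Two residual architectures are provided as
forward-only NumPy implementations with He-initialized weights drawn
from the config seed — bottleneck stages (3,4,6,3) for the 50-layer
network and (3,4,23,3) for the 101-layer one, both ending in a
2048-wide GAP tap and a fresh fully connected head sized to the label
space (seven by default). Activations after each convolution are
normalized per image and per channel (instance-norm style); this keeps
magnitudes bounded through 50+ random-weight layers while keeping each
image's features independent of the batch it rides in. Preprocessing is
a bilinear resize to `input_size` (224 native) and channel-wise
standardization with mean 0.5 / SD 0.25; these constants are
assumptions, stated here because the extraction contract does not pin
them.

Only the head is ever trained (`fine_tune`), on GAP features, with
scikit-learn: logistic regression for the mock backbone (closed-form
speed), an SGD log-loss classifier with the configured learning rate
and epoch budget otherwise. Head training cannot change the GAP
features, so `epochs=0` trivially returns identical features and
extraction is invariant to fine-tuning state by construction. The mock
backbone is a fixed seeded Gaussian projection of the flattened resized
pixels to `feature_width` columns; it preserves linear class structure,
which is all the downstream stages assume.

## Fusion

Serial fusion concatenates two matrices over identical samples
(labels checked element-wise; widths add, n+m). The SEM rule then
summarizes each fused column j by its mean over samples, c_j, computes
the sample standard deviation s of the vector (c_1…c_d) with the n−1
denominator, sets SEM = s/√d, and keeps column j iff c_j ≥ SEM (ties
kept, matching the "≥" in the rule). Degenerate case: all summaries
equal gives s = SEM = 0 and every column is kept.

Two readings of the rule's centering term — grand mean of all entries
vs. mean of the column summaries — coincide whenever columns share a
sample count, so only the column-summary reading exists; the summary
statistic itself is pluggable (`summary_fn`) for per-column alternates.
On ReLU-derived deep features all c_j ≥ 0; on signed inputs a
negative-mean column is always discarded when SEM > 0, which is the
documented behavior, not an error. The rule compares a location
statistic to a scale statistic of the same vector, so the kept set is
invariant to multiplying all features by a positive constant.

## Selection

Pearson's second skewness coefficient, Skew = 3(mean − median)/s
(sample SD), is computed on the per-column mean vector of the fused
matrix; a column is a candidate iff its mean ≥ Skew. A constant mean
vector makes the coefficient undefined (s = 0); the screen then selects
every column and warns rather than failing, since there is nothing to
rank.

Candidates are validated by a fitness function: an ε-insensitive SVR
with Gaussian RBF kernel is fit on a seeded stratified 70:30 split
(reusing the protocol's global split ratio) with labels encoded as
consecutive integer codes; held-out predictions are rounded to the
nearest code (clipped to the code range) and fitness is the fraction
correct. Defaults, stated as this package's choices: C = 1, ε = 0.1,
kernel width γ = 1/(2ρ²) with ρ the median pairwise training distance
(estimated on ≤200 rows for cost).

The loop: if fitness < target (default 0.90) and iterations remain
(default 5), the threshold is relaxed and fitness re-evaluated; the
best candidate set seen is returned with the full trace. Relaxation is
multiplicative toward −∞ — thr·0.8 when thr ≥ 0, thr/0.8 when thr < 0 —
because a plain multiplication of a negative threshold would raise it
and shrink the candidate set, breaking the loop's purpose of admitting
features until fitness clears the target. Candidate sets are therefore
monotonically non-shrinking across iterations. An optional
`n_features_cap` truncates the final set to the top columns by mean,
for sweeps over fixed selected widths; the canonical path is the
iterative procedure.

## Evaluation

Two protocols are implemented — stratified 70:30 holdout and stratified
k-fold CV (k = 10 default, reduced with a warning when the smallest
class is below k) — and every report records which one produced it.
The ten-member zoo uses the conventional presets the classifier names
denote in common GUI toolboxes, all overridable: linear / quadratic /
cubic / medium-Gaussian SVMs (standardized inputs), cosine KNN (k=10),
coarse KNN (k=100, clipped to the training size), distance-weighted KNN
(k=10), random-subspace discriminant and random-subspace KNN ensembles
(30 learners, half the features, no bootstrap), and boosted trees
(AdaBoost, 30 depth-3 trees).

Metrics come from the (fold-pooled) confusion matrix: macro recall and
precision in percent, FNR = 100 − macro recall (exact, pre-rounding),
accuracy = trace/total, F1 = harmonic mean of the macro rates. AUC is
macro one-vs-rest from decision scores when the classifier exposes
them; otherwise a trapezoidal surrogate from the per-class (TPR, FPR)
point of the confusion matrix. Macro (not weighted) averaging is the
package's choice and is flagged here. Wall time is reported per
classifier and never asserted.

## Synthetic data

The feature generator draws class blobs: informative columns get
class-dependent Gaussian means placed on a scaled simplex
(pairwise distance = `separation`, in noise-SD units, exact when the
informative dimension is at least the class count; otherwise random
directions rescaled to the right mean pairwise distance); noise columns
are i.i.d. standard normal and label-independent. `nonnegative=True`
pushes draws through a softplus to emulate ReLU-derived deep features —
the regime in which mean-based thresholding is meaningful. The image
generator renders one parametric family per class (disc radius and hue
deterministic in the class index, jittered center per image) over
speckle noise.

What passing tests show, and don't: the generators give linearly
separable, balanced, low-dimensional data with independent noise.
Success there validates the machinery (contracts, formulas,
determinism, enrichment above base rate, chance-level nulls), not
clinical performance: real dermoscopy features are correlated,
imbalanced before augmentation, and far from Gaussian, and the printed
benchmark accuracies of the original study require the external
dataset and GPU-trained weights, which are deliberately out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as this package's
defaults: balancing checked at full scale on count arithmetic and at
1/100 scale on executed images (targets 60); the residual-network
contract at its native 224-pixel input on a handful of images (the GAP
width is input-size independent, the network being fully
convolutional); selection recovery at n = 300, 8 informative + 32 noise
columns, separation 3, over 20 seeds; null behavior at separation 0
over 10 seeds. Formula checks (SEM, skewness, metric identities) are
asserted against naive loop oracles at 1e-9. Ties at a threshold are
kept. All randomness flows from explicit seeds; property tests run
derandomized.

## Known limitations

- Random-init residual features are architecture-faithful but
  untrained; they exercise contracts, not representation quality.
- The SVR-fitness discretization (rounding a regression output to class
  codes) imposes an arbitrary ordering on nominal classes; it is kept
  because it is the procedure being modeled, with the seeded split
  making it reproducible.
- The coarse-KNN preset (k = 100) degenerates on datasets with fewer
  than ~100 training rows per fold; the harness clips k and reports
  honestly rather than silently retuning.
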