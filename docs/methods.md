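# Methods

`lesionseg` implements a complete CPU-only pipeline for volumetric multiple
sclerosis (MS) lesion segmentation from multi-modal MRI (T1, T2, FLAIR):
synthetic phantom generation, preprocessing, lesion-aware patch sampling, two
3-D encoder–decoder networks, composite-loss training, connected-component
post-processing and voxel-wise uncertainty quantification. This note records
the model, its assumptions, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Data model and preprocessing

A subject is a directory of six NIfTI files: three modalities and one lesion
mask per modality. On load, axes are reordered to the closest-to-RAS
anatomical convention so flips and patch axes have a stable meaning across
files. The FLAIR grid is the reference: T1/T2 are resampled onto it with
corner-aligned linear interpolation, masks with nearest-neighbour
interpolation (so labels stay binary). The FLAIR-space mask is the single
training ground truth; which modality's annotation should serve as ground
truth is genuinely open in multi-mask datasets, and FLAIR was chosen because
MS lesions are defined hyperintensities on FLAIR.

Intensities are z-scored per modality, `I_norm = (I - mu) / (sigma + eps)`
with `eps = 1e-8`, where `mu` and `sigma` (population form, 1/N) are computed
over **non-zero** voxels only — the zero background of skull-stripped volumes
would otherwise dominate the statistics. Adding, rather than subtracting,
`eps` in the denominator keeps the map stable when `sigma ~ 0` (a constant
volume maps to zero rather than exploding). Background voxels pass through
the same affine map by default, which keeps the per-modality transform
strictly linear; a `preserve_zero_background` flag pins them back to zero.

Masks are binarized with a strict `> 0.5` comparison. Cohorts are split at
the patient level 70/15/15 by a seeded shuffle followed by
floor-and-remainder assignment (`train = floor(0.70 n)`,
`val = floor(0.15 n)`, test the rest): exhaustive and disjoint by
construction, so no patient's patches can leak across subsets. For 60
subjects this yields 42/9/9. The global class imbalance is summarized by the
lesion ratio, `100 * lesion voxels / total voxels`, pooled over the cohort.

## Phantom generator

The phantom module emulates the summary statistics of a consensus-annotated
60-subject MS cohort so every downstream stage is testable without external
data. Each subject is an ellipsoidal "brain" (semi-axes 0.44/0.42/0.40 of the
grid, ~30% of the field of view, slight center jitter) of constant
per-modality tissue intensity in a zero background. Lesions are axis-aligned
anisotropic ellipsoids with per-axis radii drawn uniformly from 2–6 voxels,
placed at uniformly drawn brain voxels (candidates poking outside the brain
are redrawn) until the voxel prevalence first reaches the target of 0.0029
(0.29%, the imbalance of the real cohort) or the lesion-count cap of 60 is
hit. The stopping rule overshoots by at most one lesion volume; on the
default 96^3 grid the pooled prevalence over 20 subjects lands within a few
percent of target, and the acceptance tolerance of ±20% relative reflects
this stochastic overshoot. Ellipsoids rather than arbitrary blobs keep the
ground-truth geometry analytic for tests.

Lesion contrast follows the MS convention: hyperintense on FLAIR (1.25 vs
brain 0.70) and T2 (1.10 vs 0.60), mildly hypointense on T1 (0.85 vs 1.00).
Degradations are a smooth multiplicative bias field — an order-3 random
polynomial scaled to `1 ± amplitude` (default 0.2) and normalized to mean 1,
so the max/min ratio is bounded by `(1+a)/(1-a)` — and additive Gaussian
noise (sd 0.05 in tissue units) applied inside the brain only, preserving the
zero-background convention. These defaults were chosen once as a plausible
clean-scanner regime: lesion-to-tissue contrast ~10 noise standard
deviations, i.e. the phantoms are deliberately easier than clinical scans.

What the phantoms do **not** model: tissue texture, cortical folding,
partial-volume effects, scanner-specific noise spectra, registration error.
Passing tests on phantoms therefore demonstrate that the pipeline's machinery
(sampling, optimization, inference, calibration bookkeeping) works, not that
clinical-grade accuracy would be reached on real data.

## Lesion-aware patch sampling

Training patches are 64^3 by default (32^3 in the scaled study). Each draw
flips a Bernoulli coin with `p_lesion = 0.5`: heads, the patch is centered on
a uniformly chosen lesion voxel; tails, on a uniformly chosen background
voxel. Centers near volume borders are clamped so every draw yields a full
patch (rejection sampling would bias away from boundary lesions); the chosen
voxel is then inside, but not necessarily at the exact center of, the patch.
Background-branch patches may still contain lesion voxels off-center — the
branch conditions the center only. A lesion-centered request on a lesion-free
subject falls back to a random center with a logged warning.

Augmentation (training streams only) applies, in order: per-axis random flips
(p=0.5 each; axial/coronal/sagittal map to the three array axes after RAS
canonicalization), one affine — isotropic scale ±10%, rotation ±10° about one
randomly chosen array axis (a single-axis rotation is exactly invertible and
testable, unlike composed Euler angles), translation ±5 voxels — with linear
interpolation for images, nearest for masks, zero fill outside the field;
then additive Gaussian noise (sd 0.03 in normalized units; "low-variance" is
otherwise unquantified) and a multiplicative bias field (amplitude 0.2) on
the image only. The mask passes only through the geometric stages, so it
remains binary and is bit-identical under intensity-only augmentation.

## Architectures

**EfficientNet3D-UNet** (the proposed network): a 3x3x3 stem to 32 channels
(batch norm + Swish), four encoder MBConv3D stages at [32, 48, 64, 96]
channels, each downsampling via a stride-2 depthwise convolution; an MBConv3D
bottleneck to 256 channels; four decoder stages at [160, 96, 64, 48], each =
trilinear 2x upsampling → 1x1x1 channel-mapping convolution → concatenation
with the encoder skip at that resolution → MBConv3D refinement → spatial
(channel-wise) dropout (rate 0.25); a biased 1x1x1 head with sigmoid. An
MBConv3D block is expansion (1x1x1, omitted at expansion factor 1 — the
default here, and squeeze-and-excitation is deliberately absent) → depthwise
3x3x3 → linear 1x1x1 projection, batch norm after every convolution, Swish
after expansion and depthwise, residual shortcut iff stride 1 and equal
channel counts. Convolutions followed by batch norm carry no bias; under this
convention the default network has **189,633** trainable parameters, within
the ~0.71M budget (the printed total cannot be reconciled exactly under every
reading of the published channel table, so the budget is enforced as an upper
bound).

**3D U-Net baseline**: stem 3x3x3 to 32 channels, four double-conv
(conv-BN-ReLU twice) encoder stages at [64, 128, 256, 512] with 2x2x2 max
pooling, a 512-channel double-conv bottleneck, transposed-convolution
upsampling with skip concatenation down [256, 128, 64, 32], dropout 0.2 in
decoder blocks, sigmoid head — 39.1M parameters. An alternate reading of the
source architecture description (256-channel bottleneck) is available as
`NetworkSpec.baseline_text_341()`.

Both networks require spatial dims divisible by 16 (four stride-2 stages) and
are built from a declarative `NetworkSpec`, with a reduced-width
`NetworkSpec.tiny()` ladder (stem 8, encoder [8, 12, 16, 24], bottleneck 32,
decoder [24, 16, 12, 8]; 15k parameters) for CPU-scale studies.

There being no GPU framework in the dependency stack, the layers (dense,
depthwise and transposed 3-D convolutions, batch norm, pooling, trilinear
upsampling, spatial dropout) are implemented directly over numpy with
explicit backward passes, realized as sums over kernel offsets of
BLAS-backed tensor contractions. Every backward pass is verified against
central finite differences in the test suite, and Adam is implemented over
the same parameter objects.

## Objective and optimization

The training loss is `L = alpha * L_Dice + (1 - alpha) * L_BCE` with
`alpha = 0.7`. The soft Dice loss uses the squared-denominator form
`1 - (2 Σ p y + eps) / (Σ p² + Σ y² + eps)` with `eps = 1e-6`, which is 0 for
a perfect match and also for the empty-prediction/empty-target pair. BCE is
the negative mean log-likelihood (the conventional sign; the loss is
non-negative and minimized at perfect prediction), with probabilities clipped
to `[1e-7, 1 - 1e-7]` before the logarithms to protect saturated sigmoids.
On binary fields the Dice overlap metric equals `1 - L_Dice` as `eps → 0`.

Optimization is Adam without weight decay, cosine-annealed learning rate
`lr_min + (lr0 - lr_min)(1 + cos(pi * (e mod T)/T))/2`. Two documented preset
pairs exist because the protocol's running text and its hyperparameter table
disagree: the table values (`lr0` 1e-4 baseline / 5e-4 proposed, cycle T=80)
are the default; the text values (3e-5 / 1e-4, T=10) are selectable as the
`narrative` preset, and the active preset is logged. Batches hold 4 patches;
the epoch length in patches is not pinned down by the protocol and defaults
to 100 configurable. Validation after every epoch computes whole-volume Dice
via sliding-window inference (overlapping 50%, uniform per-voxel averaging of
window probabilities, zero-padding cropped after stitching); the checkpoint
with the highest validation Dice is kept, and training stops early after 25
epochs without improvement. A NaN loss aborts with a diagnostic rather than
skipping batches. Evaluation thresholds probabilities at 0.5 (the protocol
binarizes ground truth at 0.5 and leaves the output threshold unstated).

Metrics (Dice, precision, recall, accuracy, specificity) derive from voxel
confusion counts; 0/0 ratios are reported as 0 with an `undefined` flag so
cohort aggregation stays total. Cohort summaries pool voxels across subjects
by default (per-subject rows are also emitted), since whether published
cohort scores pool or average is not stated.

## Post-processing and uncertainty

Predicted masks are cleaned by removing connected components smaller than
`min_voxels` (default 5 voxels — the protocol does not quantify "small" — at
26-connectivity; both configurable and logged). The operation is idempotent,
monotone in the threshold, and is verified against a brute-force BFS
flood-fill oracle.

MC-dropout inference keeps the spatial dropout layers active (p = 0.25 in
the proposed network) and averages 30 stochastic sliding-window passes; the
uncertainty is the binary predictive entropy of the MC mean (not the mean of
per-pass entropies — "predictive mean and entropy" reading). Deep-ensemble
inference averages five independently seeded members and reports the
voxel-wise population variance (bounded by 0.25) as uncertainty. Calibration
is summarized by the Expected Calibration Error over 10 equal-width bins of
the max-probability confidence, voxels pooled across evaluated subjects, plus
the point-biserial (Pearson) correlation between uncertainty and the
misclassification indicator.

## The scaled study

The acceptance-level end-to-end study trains the reduced-width network on
eight 48^3 phantom subjects (split 5/1/2 by the standard splitter) with 32^3
patches, 15 epochs of 48 patches, `lr0 = 3e-3` annealed over the run. The
full-size learning rates are tuned to the 0.19M-parameter network and a
many-epoch schedule; the 15k-parameter study model on high-contrast phantoms
trains stably at the larger rate, and these sizes keep the whole study in the
low minutes on one CPU core. Under this configuration the held-out pooled
Dice lands far above both trivial references (the all-background predictor
and a prevalence-rate Bernoulli predictor), and a single patch can be
overfitted to Dice ≈ 1, which is the intended demonstration: the optimizer,
loss and architecture wiring are sound at reduced scale.

## Numerical notes and limitations

- Batch-norm uses population (biased) variance for both batch and running
  statistics; running stats update with momentum 0.1. With very small
  spatial extents (e.g. a 1^3 bottleneck on 16^3 patches) batch statistics
  degenerate and train/eval behaviour can diverge — the study uses 32^3
  patches, keeping the bottleneck at 2^3.
- Max pooling distributes gradients uniformly over tied maxima; ties have
  measure zero on continuous activations.
- Trilinear upsampling is the separable half-voxel-aligned 2x kernel
  (0.75/0.25), with its exact adjoint as the backward pass.
- Sliding-window stitching uses uniform window weights; per-voxel weights
  sum to 1 exactly, verified by a constant-emitting probe network.
- All randomness flows through `numpy.random.Generator` seeded per
  component; end-to-end runs are bit-reproducible single-threaded.
- The phantom study demonstrates machinery, not clinical performance;
  published cohort-level scores on the real 60-subject dataset are out of
  scope here (they require the external cohort and GPU-scale training).
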