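# Methods

## Model

A volume is classified in five stages.

**1. View and normalization.** The volume is min-max normalized to [0, 1]
per volume (constant volumes map to zero) and permuted so the chosen
anatomical axis is the fusion axis — a pure axis permutation, never a
resample. For a canonically stored (96, 160, 160) array the default
mapping is axis 0 = axial, axis 1 = coronal, axis 2 = sagittal, giving
fused images of 160 × 160 (axial) and 96 × 160 (coronal and sagittal).
Which of the two 160-sized axes is coronal versus sagittal is convention-
dependent across archives, so the mapping is a configuration entry rather
than a constant. Min-max normalization is likewise a package choice: it
makes the slice network's input scale-free without assuming anything about
the acquisition units. Z-scoring is available as an option.

**2. Slice scoring and fusion.** The slice network ψ is a shared-weight
CNN applied to each slice independently: four 3 × 3 stride-2 convolutions
with ReLU (default widths 8, 16, 32, 64), global average pooling, and a
linear map to one scalar. The architecture beyond "four convolutions plus
global average pooling" is a design choice here; the widths keep the
added cost a small fraction of a ResNet-scale backbone, consistent with
learnable pooling being a cheap increment over fixed pooling, and they are
configurable. Weights are Kaiming-initialized from a seed. Slice scores
are softmax-normalized with max-subtraction (the textbook softmax
overflows for large logits) and the fused image is the convex combination
of slices. Fixed poolings: pixel-wise max, pixel-wise mean, and
approximate rank pooling with plain coefficients α_t = 2t − T − 1. The
`time_averaged` ARP variant applies those coefficients to running means
(1/t) Σ_{τ≤t} I_τ, equivalently per-slice coefficients
c_τ = Σ_{t≥τ} (2t − T − 1)/t; the plain form is the default because it is
the stated coefficient formula, and which variant any given baseline used
historically is ambiguous.

**3. Channel adaptation.** The fused single-channel image is replicated to
three identical channels so standard 2D backbones apply; no resizing, as
the backbones are fully convolutional down to global pooling.

**4. Attention.** A dual-attention block refines the final backbone
feature map, before global pooling. The self-attention branch is an
embedded-Gaussian non-local block: 1 × 1 query/key/value projections with
bottleneck ratio r = 2, scaled dot-product attention over the N = H′·W′
positions (each row of the attention matrix is a probability vector), and
a zero-initialized 1 × 1 output projection added residually — so an
untrained block is exactly the identity, which stabilizes the start of
training. The channel branch is the cost-efficient 1D-convolution form:
spatial mean per channel, a single odd-sized kernel (default k = 3,
zero-padded, no bias) convolved across channels, a sigmoid gate in (0, 1),
and channel-wise multiplication. The block output is the element-wise
*sum of the two branch outputs* (each branch already carries the input via
its residual/gating structure), not input + SA + CA; "sum fusion" is read
as merging the two sub-module outputs. Ablation modes `none`/`sa`/`ca`/
`dual` correspond to the backbone-only and single-branch configurations.

**5. Classifier.** Global average pooling to the backbone feature width,
then FC(512) → BN → ReLU → dropout(0.5) → FC(64) → BN → ReLU →
dropout(0.5) → FC(2). The activation between layers is unstated upstream;
ReLU is the package's choice. The two logits pass through a softmax and
the positive-class probability feeds the loss. How the C × H′ × W′
attention output becomes the FC input is also unstated; global average
pooling is used because it matches the FC widths for a 512-channel
backbone and adds no parameters.

## Loss and training

The loss is weighted binary cross-entropy,
loss = −[w_p·l·log p + w_n·(1−l)·log(1−p)], with probabilities clamped to
[1e-7, 1 − 1e-7]. The printed form of this loss in the source literature
lacks the leading minus sign; it is implemented negated since maximizing
log-likelihood means minimizing its negation. Class weights default to
"auto": w_n = 1, w_p = n_neg/n_pos computed from the training split (a
fixed override such as 1.28 is accepted). Optimization is Adam with
β₁ = 0.9, β₂ = 0.999; the replication defaults are batch 16, learning rate
1e-4, 150 epochs. All parameter groups — slice network, backbone,
attention, classifier — are updated jointly.

**BatchNorm recalibration.** During optimization BatchNorm normalizes each
batch with its own statistics while exponentially averaged running
estimates trail the moving parameters. When between-sample feature
differences are small (exactly the phantom regime, where volumes differ
only in a localized blob), that trailing error can drown the signal at
inference. After the last epoch the package therefore runs one forward
pass over the whole training set as a single batch with dropout off and
momentum 1, resetting the running statistics to the exact training-set
statistics. This is a standard recalibration (familiar from stochastic
weight averaging); it touches no trainable parameter. It processes the
training set in one batch, which bounds the supported training-set size by
memory; at the package's default problem sizes this is a few tens of MB.

**Cross-validation.** Stratified K-fold (default K = 5): each class is
shuffled with the fold seed and split into K near-equal chunks, and each
class's remainder goes one-by-one to the currently smallest folds. This
guarantees per-class counts within 1 of proportionality *and* total fold
sizes differing by at most 1 (a per-class round-robin alone can violate
the latter — e.g. 381 samples split 214/167 would give fold sizes
{77, 77, 76, 76, 75} instead of {77, 76, 76, 76, 76}). Stratification
itself is a package choice motivated by class imbalance. Per-fold models
are trained on K−1 folds and score the held-out fold; the headline report
pools the out-of-fold predictions (every sample scored exactly once by a
model that never saw it), with per-fold reports and fold-mean metrics
returned alongside, since either aggregation convention is defensible.
No learning-rate schedule, early stopping, or augmentation is applied.

## Metrics

Confusion counts use threshold 0.5 on the positive-class probability with
ties predicted positive. Accuracy, precision, recall and F1 follow the
standard confusion-matrix formulas; a 0/0 ratio is reported as 0 with a
warning flag (this arises only in degenerate folds). ROC-AUC is the
rank-based probability that a random positive outscores a random negative
(ties count 1/2) and AP is the step-interpolated weighted mean of
precision over recall increments — both computed via scikit-learn and
cross-checked in the test suite against brute-force pair counting and an
exhaustive threshold sweep.

## Numerical engine

No deep-learning framework is assumed: `slicefuse._nn` is a compact
reverse-mode autodiff over numpy (tape of tensors with backward closures),
with im2col convolution, max pooling, batch normalization, dropout, the
attention primitives, and Adam. The engine runs in float32 by default —
adequate for training at these scales and measurably faster on CPU — and
can be switched to float64, which the test suite does when comparing
analytic gradients of every layer against central finite differences.
Multiply-add (MADs) accounting is instrumented into the compute-bearing
primitives: a counted forward pass sums k_h·k_w·C_in·C_out·H_out·W_out per
convolution and the inner-product volume per matrix product, so the count
always reflects the executed architecture. Parameter-free poolings and
normalizations count zero; consequently max/avg/ARP configurations of the
same backbone tie exactly and the LWP configuration exceeds them by
precisely the slice network's cost.

Backbones `tiny` (four stride-2 convs, widths 16–128), `resnet34` and
`vgg11` are built in this engine with seeded random initialization.
Pretrained ImageNet weights are not bundled, so `pretrained=True` raises;
fine-tuning from a checkpoint is supported instead. The densenet121 /
mobilenet_v2 / efficientnet identifiers are recognized but raise a clear
"not available in this build" error.

## Synthetic phantoms

The generator emulates the one statistical property learnable slice
pooling exploits: class-discriminative signal concentrated in a band of
slices. Each phantom is an ellipsoidal brain (80% of each dimension) at
background 1.0 inside Gaussian noise (SD 0.1); positive volumes subtract
an amplitude-1.0 ellipsoidal blob confined to the band (default: the
middle third of the fusion axis) and to the brain mask. Labels are
balanced and the dataset is bit-reproducible from (spec, seed).
`band_contrast` — the absolute difference of class-mean slice intensities
per slice — recovers the band without any model and is the oracle against
which learned α profiles are compared.

What the phantoms deliberately lack: anatomy, tracer kinetics, scanner
point-spread, inter-subject registration error, and any overlap between
the class distributions. Passing tests on phantoms therefore demonstrate
that the machinery is correct — gradients reach the slice network, weights
concentrate where signal is, cross-validation is leak-free — not that any
particular accuracy transfers to real cohorts.

## Problem sizes and defaults

The phantom study protocol used by the tests and `scripts/acceptance.py`:
40 volumes per class of 24 × 32 × 32 voxels, band 8–15, amplitude 1.0 /
noise 0.1, tiny backbone with dual attention, 15 epochs of Adam at
learning rate 1e-3, batch 16, 5-fold stratified cross-validation, and
three independent seeds for the weight-recovery comparison. The 1e-3 rate
is deliberate: the replication default of 1e-4 is a fine-tuning rate for
pretrained backbones, whereas the tiny backbone trains from scratch; with
clear class separation the loss plateaus within a handful of epochs, so 15
epochs is comfortably convergent. These sizes keep a full cross-validated
run in the low minutes on a single CPU core.

## Known limitations

- Full-batch BatchNorm recalibration bounds the training-set size by
  memory (chunked recalibration would change the estimates only by
  floating-point accumulation order, but is not implemented).
- The slice network's internals (kernel sizes, widths) and the attention
  bottleneck are fixed by package convention where the source description
  is silent; absolute MADs values are therefore not comparable across
  implementations — only the structural relations (ties among fixed
  poolings; LWP increment = slice-network cost) are.
- `resnet34`/`vgg11` run but are slow to train in a numpy engine; they are
  intended for architecture-level checks and MADs accounting, with `tiny`
  as the practical training backbone.
- Single-channel volumes only; multi-label and multi-class tasks are out
  of scope.
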