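# Methods

## Problem setting

During flexible ureteroscopy the navigable path appears in the endoscopic
image as the *lumen*: a dark, roughly elliptical "tunnel" region whose
center is the least-illuminated part of the field of view, surrounded by a
brighter, reddish, textured ureter wall.  Automatic per-pixel lumen
segmentation supports navigation assistance, and is complicated by blur,
specular highlights, floating debris, bleeding, and occlusions.  Because
consecutive video frames change only minimally, a frame whose own content
is momentarily useless (debris flashing across the field of view, a
corrupted frame) can still be segmented from its temporal neighbors —
this is the central mechanism the package implements and demonstrates.

## Models

**m1 — residual U-Net.**  An encoder–decoder with skip connections whose
blocks are residual units: two 3×3 convolutions (batch-normalized) with an
identity shortcut, a 1×1 projection when channel counts change, and a ReLU
after the sum.  Downsampling is 2×2 max pooling, upsampling a 2×2 stride-2
transposed convolution, and the head a 1×1 convolution with a sigmoid that
emits one lumen-probability channel.  The spec exposes `depth` (encoder
levels), `base_filters` (doubling per level), input shape (spatial dims
must be divisible by 2^depth) and batch-norm use.  Defaults: depth 4, base
32 at a 256×256 working resolution; the synthetic study uses depth 3, base
16 at 64×64.

**m2 — instance-segmentation core.**  A compact detect-and-segment model:
a plain double-conv encoder–decoder FCN proposes a per-pixel foreground
probability field; connected components of the field (at proposal
threshold 0.5) become candidate instances, each carrying a soft mask (the
probability field restricted to the component) and a score (its mean
interior probability).  Candidates are filtered by a minimum detection
confidence (configurable in [0.5, 0.9]) and by size priors derived from
the anchor scales (default 32, 64, 128, 160 pixels: components larger in
extent than twice the largest scale, or smaller than 4 px, are dropped).
The adapter `instances_to_lumen_map` merges survivors into a single lumen
probability map — `best` keeps the highest-scoring instance (the lumen is
one region in this anatomy), `union` takes the pixelwise maximum.  The
`backbone` choice (resnet50/resnet101) selects the encoder width.  The
stem's channel count is fixed at construction, mirroring the frozen input
contract of a pretrained backbone; this matters for the temporal extension
below.

**Temporal extension m → M.**  Any core model is extended to a
spatio-temporal one by prepending a single 3D convolution over a triplet
of consecutive frames (I(t−1), I(t), I(t+1)).  With temporal extent r = 3
and kernels of size (r×3×3), the valid convolution consumes the whole
temporal axis and yields a block of shape (1, p−2, q−2, n_k); one pixel of
zeros is padded on each spatial border (symmetric split) and the singleton
axis squeezed, so a (p, q, n_k) block feeds the core directly.  The added
parameter count is exactly n_k·(r·3·3·n_c) weights + n_k biases (246 for
n_k = n_c = 3).  For M1 the U-Net stem is rebuilt to accept n_k channels
and n_k is a searched hyperparameter (default search set {3, 8, 16}); for
M2 the fixed 3-channel stem forces n_k = 3, which is enforced at
configuration time.  The activation after the front convolution is ReLU by
default (linear available for ablation); either choice preserves the
exactly-zero border ring.

**Ensemble.**  The final prediction is the arithmetic mean of the k member
probability maps, F(p_i(t)) = (1/k)·Σ p_i(t), computed on soft
probabilities — members are never thresholded before fusion.  The fused
map is binarized at 0.5 (the natural decision boundary for a mean of
probabilities; the threshold is configurable).  Every subset of
{m1, m2, M1, M2} runs through the same code path, so single models, the
four two-member ablation variants and the full four-member ensemble are
directly comparable.

## Loss and metrics

Training minimizes a differentiable soft-Dice loss,
1 − (2·Σ p·g + ε)/(Σ p + Σ g + ε) with ε = 1e−6 — small enough not to
perturb the third decimal at 64×64 while keeping the loss defined for
empty masks.  Evaluation uses hard pixel counts: DSC = 2TP/(2TP+FP+FN),
precision TP/(TP+FP), recall TP/(TP+FN), computed per frame at native
resolution and aggregated as means and quartiles over frames (never pooled
over pixels).  When both prediction and truth are empty, DSC, precision
and recall are 1 by convention (agreement on absence is agreement; the
value is configurable).  Per-frame DSC distributions of different models
are compared with the Kruskal–Wallis rank test (omnibus and pairwise, with
the usual */**/*** annotation at 0.05/0.01/0.001).

## Training protocol

Adam (searched learning rate, default 1e−3) minimizes soft-Dice; epochs
default 50 with early stopping (patience 10 on validation DSC) in the
library defaults, and far fewer in the synthetic study (see below).  Model
selection is by mean validation DSC over patient-wise k-fold
cross-validation: patients are partitioned so that no patient's frames
ever appear on both sides of a fold; augmented copies inherit their source
frame's patient label, so the guarantee survives offline augmentation.
The hyperparameter grids are lr ∈ {1e−3, 1e−4, 1e−5, 1e−6} ×
bs ∈ {4, 8, 16} (plus n_k for M1, and backbone × detection-confidence for
m2); ties break toward the smaller learning rate, then the smaller batch
size, and the winning combination is re-derivable from the emitted CV
table alone.  The final fit uses the selected hyperparameters on a 60/40
train/validation split of all training-patient frames — frame-random
stratified by video by default (a patient-wise option exists, since either
reading of a frame-level split is defensible).

Augmentation is offline (run before training): rotations in steps of 90°,
horizontal/vertical flips, and zoom in a ±2% range, sampled once per
(video, copy) and applied identically to every frame of that copy and its
masks (bilinear for images, nearest-neighbor for masks, so masks stay
binary and triplets stay temporally coherent).  Zoom rescales about the
center and center-crops (in) or zero-pads (out) back to the original
shape.  Default: 4 augmented copies per original.

One master seed fans out deterministically to fixture generation, weight
initialization, shuffling and augmentation; with a fixed seed the whole
simulate → train → evaluate pipeline is bit-reproducible on one machine.

## Synthetic data generator

Real ureteroscopy data are not redistributable, so the package ships a
generator that emulates their statistical structure: a brighter reddish
wall with smooth multiplicative texture and radial illumination falloff
centered near the lumen; a dark ellipse whose center follows a smooth
two-frequency drift path and whose semi-axes jitter slowly; and the
artifact taxonomy of endoscopic video — specular white blobs on the wall,
semi-transparent debris, defocus blur, a bleeding red tint, and optional
full-frame noise corruption of isolated center frames (never two adjacent,
never a video's first or last frame, so the temporal neighbors stay
intact).  The ground-truth mask is the exact ellipse interior, giving a
closed-form area oracle; the rendered rim is slightly soft so the learning
task is not a trivial threshold.  In every clean frame the lumen interior
is strictly darker than the wall.  The default dataset mirrors a
multi-video clinical collection: 6 synthetic patients over 11 videos
(several patients contributing multiple videos), per-video appearance
diversity drawn around the template, and per-video child seeds spawned
independently of generation order.

What the generator deliberately does not reproduce: real tissue texture
and vasculature, specular geometry of wet surfaces, camera optics,
non-elliptical lumen shapes (a deformable boundary is approximated only by
axis jitter), and inter-patient anatomy differences beyond appearance
parameters.  Passing the synthetic studies therefore shows that the
architecture, losses, CV protocol and ensemble plumbing behave correctly
and that the temporal pathway carries information — not that clinical
performance figures transfer.

## Study problem sizes

The shipped studies are sized for minutes-scale runs on one CPU: 64×64
frames, 11 videos × 42 frames, the four-video patient P6 held out
(≈ 294 training-pool frames, 168 test frames), m1 at depth 3 / base 16,
6 training epochs with patience 5, lr 1e−3, bs 8.  The temporal-recovery
study corrupts 30% of center frames and compares m1 with M1 (n_k = 8)
trained identically; the ablation study trains all four members briefly
(4 epochs, 12 frames per video) since it checks comparability of the
ensemble code paths rather than peak accuracy.  The Kruskal–Wallis
calibration uses 1,000 null replicates of three 30-sample groups.

## Numerical choices and edge cases

- The neural-network layer under all models is the package's own
  NumPy-based reverse-mode autodiff engine (`lumenseg.nn`): channels-last
  im2col convolutions backed by BLAS matmul, max-pool with explicit argmax
  bookkeeping, train/eval batch norm with running statistics, and Adam
  with bias correction.  Every op's backward is verified against central
  differences in the test suite.
- Weight init is He-normal, always from an explicit generator.
- Frames are normalized by their dtype maximum at read time (255 → 1.0),
  so losses are independent of bit depth.
- Videos differ in native size; within a video all frames must agree.
  Model inputs are resized (bilinear; masks nearest-neighbor) to a fixed
  square working resolution and predictions resized back before scoring.
- Triplet boundary policy: `replicate_edge` by default (every annotated
  frame is segmentable, the first triplet being (I0, I0, I1));
  `drop_edges` is available for strict-causality experiments.
- Binarization uses the ≥-threshold convention (a pixel exactly at the
  threshold is foreground).
- A zero learning rate is a valid control: Adam performs no update.
- Non-finite training loss raises a divergence error immediately rather
  than silently continuing.

## Known limitations

- The instance core is a compact detect-and-segment design, not a full
  region-proposal/RoI architecture; its backbone is trained from scratch
  with the Dice objective rather than fine-tuned from large-scale
  pretraining, so conclusions about pretrained-backbone behavior (e.g.
  how much the fixed-input constraint costs M2) are qualitative.
- Inference is CPU-bound and unoptimized for real-time use.
- The ensemble is an unweighted mean; weighted or learned fusion is out
  of scope, as are temporal extents other than r = 3.
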