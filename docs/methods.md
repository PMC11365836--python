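# Methods

## Problem and model

`ivdseg` implements self-supervised domain adaptation for binary 3D
segmentation of intervertebral discs (IVDs) in T2-weighted MRI-like volumes.
The practical obstacle it addresses is intensity domain shift: volumes
acquired on different scanners or protocols have systematically different
noise levels, contrast curves and illumination (bias) fields, and a
segmentation network trained on one labeled source domain S degrades on
unlabeled target domains T1, T2.

The model is a dual-task 3D encoder–decoder:

- **Encoder e(·)** — four blocks of two 3×3×3 same-padded convolutions, each
  followed by ReLU then batch normalisation, then a 2×2×1 max pool. Channel
  widths double per block, 32 → 256 at full width, followed by a two-conv
  512-channel bottleneck. Pooling acts only in-plane because the slice axis
  is short and anisotropic.
- **Decoder d(·)** — the mirror path: 2×2×1 nearest-neighbour upsampling,
  concatenation with the matching encoder feature map, and two convolutions
  per block (256 → 32); the last block has three convolutions, the final one
  producing a 2-channel per-voxel softmax. The foreground mask is the voxel
  argmax.
- **Pretext head i(·)** — reads the bottleneck features through three blocks
  of two convolutions (256 → 128 → 64 filters at full width, ReLU + batch
  norm), a final convolution down to C=4 channels, global average pooling
  and a softmax over the four intensity-transformation classes. A second,
  identical branch can be attached for the rotation pretext (4 classes:
  0/90/180/270°).

The pretext task manufactures labels for free: an unlabeled volume from any
domain is distorted by one of {identity, Gaussian noise, Gaussian blur,
contrast enhancement} and the head must recover which. Because the head sits
on the shared encoder, solving this task on S, T1 and T2 jointly pushes the
encoder toward features that encode intensity statistics explicitly — and
therefore generalise across intensity-shifted domains — while the decoder is
trained on the labeled source only.

Training optimises `L_total = L_seg + L_p`: soft Dice on the segmentation
output (robust to the extreme class imbalance of small discs) and
cross-entropy on the pretext head. Each iteration pairs one segmentation
batch (size 1) with one pretext batch (size 4), back-propagates both losses
so their gradients accumulate on the encoder, and takes a single Adam step
with a fixed learning rate (default 0.001; the CPU-scale benchmark uses
5e-4 — at quarter width with batch-1 gradients the larger step makes
checkpoint quality oscillate between adjacent epochs). One epoch is one
pass over the source training pool; the
retained checkpoint is the epoch minimising validation `L_total` on the
source validation split, with the pretext validation samples frozen (same
samples, same draws every epoch) so the criterion is comparable across
epochs.

### Design choices where the architecture was open

- *Layer order* is conv → ReLU → batch-norm, the literal reading of the
  architecture description this follows, although conv → BN → ReLU is more
  common. Decoder blocks carry no batch norm.
- *Upsampling* is parameter-free nearest-neighbour repetition (no transposed
  convolution).
- *Head aggregation*: the head's final conv keeps spatial extent, so a
  per-volume class distribution needs a spatial reduction; global average
  pooling over the logits is used — minimal and parameter-free.
- *One optimiser step per iteration*, on the summed gradients, rather than
  two interleaved task steps: the simplest scheme consistent with "gradients
  accumulated at the encoder", and exactly the unweighted `L_total` step.
- *Pretext batches mix domains round-robin* (S, T1, T2 alternating) so every
  step sees balanced domain exposure.
- *Geometric pretext augmentation runs before the intensity distortion* —
  the only order that provably leaves the pretext label semantics intact.
- Loss weights default to 1:1 (`L_total = L_seg + L_p`); they are
  configurable for sensitivity checks and for the gradient-routing tests.

## Intensity transformation bank

Magnitudes are free parameters of the method; they must be large enough that
the four classes are reliably separable by the encoder and small enough that
anatomy is preserved. Defaults, drawn uniformly per sample:

| transform | parameter | default range | units |
|---|---|---|---|
| Gaussian noise | σ | 0.2 – 0.3 | fraction of the [0,1] intensity range |
| Gaussian blur | σ | 1.2 – 2.2 in-plane, half through-plane | voxels |
| contrast enhancement | k in v ↦ clip(0.5 + k(v−0.5)) | 2.5 – 3.5 | – |

Two constraints shaped these choices, both consequences of applying the
pretext task across domains whose *own* differences are intensity
differences. First, the noise class floor must clearly exceed the noisiest
domain's intrinsic noise (σ = 0.12 in the benchmark), otherwise "identity on
a noisy domain" and "mild noise on a clean domain" are the same image and
the class boundary is ill-posed. Second, contrast enhancement must not be a
gamma map: the domains differ by gamma, so a gamma-transformed volume from
one domain can exactly impersonate an untransformed volume from another.
The saturating linear stretch about mid-grey produces contiguous clipped
plateaus at 0 and 1 — a histogram signature that no smooth acquisition
difference (gamma, bias, noise) reproduces. Classifiability of these
defaults is verified by the held-out pretext-accuracy test (≥ 90 %).
Exactly one transform is applied per pretext sample — labels are
single-class under a 4-way softmax.

Segmentation-stream augmentation: horizontal flip, ±30° in-plane rotation
(linear for the image, nearest-neighbour for the mask) and ±0.15 brightness
shift, each independently with probability 0.5 per iteration. The pretext
stream uses only vertical flip and ±30° rotation, resampled by nearest
neighbour: linear interpolation would smooth the volume and corrupt the
identity/noise/blur label semantics. The 90° rotation pretext uses lossless
index permutations so the class is exactly recoverable.

## Synthetic phantom domains

No MRI data ships with the package; a generator emulates the *structure* of
the problem. A phantom is a stack of bright ellipsoidal discs (wide
in-plane, thin along the spine axis, aspect 0.4; 5–7 by default depending on
grid size) with jittered spacing along a sinusoidally curved vertical axis,
on a darker textured background, softened by a small Gaussian to imitate
partial-volume boundaries. The intensity pipeline is: ideal image →
background texture → multiplicative low-frequency bias field (sum of three
random low-order cosine modes, normalised) → additive Gaussian noise →
clamp to [0,1] → per-domain gamma → clamp.

Geometry and intensity use two independent seeded RNG streams, so two
domains that differ only in (noise σ, γ, bias amplitude) generate *identical
masks* for identical seeds: the domain shift is purely an intensity shift,
by construction. Defaults: foreground mean 0.75, background 0.30, expected
foreground fraction ≈ 3 % of the volume.

The benchmark domains (`desk_scale_config`) are:

| domain | noise σ | γ | bias amplitude | role |
|---|---|---|---|---|
| S | 0.03 | 1.0 | 0.05 | labeled source |
| T1 | 0.08 | 0.6 | 0.25 | unlabeled target, brightened |
| T2 | 0.12 | 1.8 | 0.35 | unlabeled target, gamma-compressed + heavy noise (the harder shift) |

What the phantoms deliberately do *not* model: real disc/vertebra anatomy,
pathology, multi-class labels, through-plane geometry changes, or MR-physics
artifacts (ghosting, spikes). Passing the benchmark therefore shows that the
*mechanism* — intensity-pretext training producing intensity-robust
segmentation — works end-to-end; it does not certify clinical performance.

## Normalisation statistics

Layer statistics are where domain shift, small batches and short schedules
interact, and three distinct conventions are used deliberately:

- **Encoder and decoder: batch normalisation with calibrated inference
  statistics.** Training normalises with current batch statistics. For
  inference, exponential running averages are unsuitable at a few hundred
  updates per run — they track the last handful of batches, so eval-mode
  outputs depend on recent batch composition. Instead, after checkpoint
  selection the model runs one deterministic frozen-weight pass over its own
  training streams (one pretext batch per segmentation batch, mirroring the
  training composition) and averages the batch statistics — the same
  re-estimation used after stochastic weight averaging. A model trained
  only on the source calibrates only on source batches; its statistics
  misnormalise shifted targets, which is precisely the baseline failure
  mode the method addresses. The dual-task model's calibration includes its
  multi-domain pretext stream.
- **Pretext head: per-sample (instance) normalisation.** Classification of
  a single volume must not depend on which other volumes share its batch
  or on externally estimated statistics, so each head feature map is
  normalised by its own spatial moments (train and eval identical).
- **Validation** (the `L_total` selection criterion) runs with batch
  statistics on a frozen validation set, making selection smooth and
  deterministic rather than hostage to the statistics state at epoch end.

## Problem sizes

The package's standard benchmark runs entirely on one CPU core with the
numpy-based network engine, so its sizes are chosen for that regime:
32×32×12 voxel volumes, width_scale = 1/4 (channel widths 8…128), 24 source
training / 6 validation / 8 test volumes, 12 unlabeled training + 8 test
volumes per target, 24 epochs, three independent seeds, comparing the
baseline single-task U-Net against the intensity-pretext model with pretext
on S∪T1∪T2 (~5 minutes per seed). Lower spatial resolution with more
optimisation steps proved a better trade than the reverse: the pretext head
needs several hundred updates to converge, while the disc geometry survives
downsampling. Full-width 256×256×18 operation is supported by the same code
path (`width_scale=1`, `preprocess` to shape) but is not exercised by the
test suite.

## Metrics and numerical conventions

- **DSC** 2|P∩T|/(|P|+|T|), defined as 1 when both masks are empty.
- **HD** symmetric max over foreground voxels of nearest-neighbour Euclidean
  distance, in isotropic voxel units, over full voxel sets (no surface
  extraction); HD95 available via `percentile=95`. An empty *prediction*
  during evaluation is recorded as the volume diagonal and flagged rather
  than crashing the run; an empty truth mask raises.
- **Sen/Spec** TP/(TP+FN), TN/(TN+FP) with the empty-denominator conventions
  Sen=1 for empty truth, Spec=1 for all-foreground truth.
- Aggregates are mean ± *population* standard deviation over volumes.
- Dice loss uses ε = 1e-6 in numerator and denominator; cross-entropy floors
  probabilities at 1e-12; normalisation layers use ε = 1e-5; Adam β =
  (0.9, 0.999), ε = 1e-8. He fan-in weight initialisation with a settable
  seed. All computation is float32.

## The numpy network engine

No deep-learning framework is part of the dependency set; `ivdseg.nn` is a
small trainable-layer engine written on numpy/BLAS with hand-derived
backward passes. Convolutions are evaluated as 27 shift-and-matmul
accumulations over the flattened zero-padded volume — every kernel tap is a
contiguous slice, so each GEMM runs on contiguous memory and tap shifts that
cross row/volume boundaries only touch cropped padding positions. Backward
passes were validated against central finite differences in float64 (the
test suite re-runs this check). Determinism: identical seeds and inputs
reproduce loss histories bit-identically in single-threaded execution; with
a multi-threaded BLAS, reduction order may vary at the last ulp.

## Known limitations

- Hausdorff distances are in voxel units; physical spacing from NIfTI
  headers is carried through I/O but not applied to metrics.
- Batch norm at segmentation batch size 1 normalises over spatial axes
  only; together with calibrated inference statistics this differs from
  large-batch BN with running averages, and is documented above.
- The benchmark's effect size (dual-task minus baseline target DSC) is
  modest by design — the phantom task is easy enough for the baseline to
  partially succeed; the comparison is about ordering, not the absolute gap.
- Empty pretext-domain lists silently mean "baseline"; this is intentional
  and validated, but configurations cannot mix baseline and pretext training
  within one model.
- At the benchmark's quarter-width scale the held-out pretext accuracy of
  the selected checkpoint varies by seed in roughly the 0.83–0.92 range:
  the residual errors are identity-vs-noise and contrast-vs-noise decisions
  on the noisiest target domain, whose intrinsic noise borders the noise
  class. Full-width training with longer schedules separates these further;
  the desk-scale runs sit at the edge of the 90 % mark rather than safely
  above it.
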