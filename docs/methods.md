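# Methods

`murivess` segments blood vessels in micro-MRI stacks of murine brains.
This note documents the models and procedures implemented, the defaults
and why they were chosen, and what the synthetic phantoms can and cannot
establish about behaviour on real data.

## Problem setting

The target data are ex-vivo gadolinium-perfused mouse-head stacks
(uint16, typically 400×400×320 voxels) in which vessels appear as *dark*
tubular structures inside bright brain tissue. Vessel voxels are
extremely rare — 0.036 %–0.134 % of the stack — so the task is a
severely imbalanced voxelwise binary classification restricted to a
manually prepared brain mask. Acquisitions differ strongly in brightness
(one stack in the reference dataset has a ~3.4× higher mean than the
rest), and the first and last ~3 % of slices carry no anatomy.

## Pre-processing

Fixed order: mask-crop → pad → blur → normalise → patchify.

1. **ROI extraction** — crop to the bounding box of the brain mask;
   voxels inside the box but outside the mask are zeroed, so nothing
   outside the brain can influence training or inference.
2. **Padding** — each axis is zero-padded *at the high-index end only*
   to the smallest multiple of the patch edge (32). "Smallest multiple
   ≥ length" is a no-op for already-divisible axes; padding on one side
   keeps the crop offset as the single number needed to invert the
   mapping.
3. **Gaussian blur** — isotropic σ = 0.5 voxels, reflecting boundaries.
   Whether to blur before or after zeroing non-brain voxels is
   genuinely open; we zero first and use reflective boundaries, which
   avoids bleeding non-brain intensities inward while keeping the blur
   well-defined at the brain edge.
4. **Min–max normalisation** to [0, 1] — computed per stack over the
   whole padded ROI, not per patch; per-patch ranges would destroy
   intensity comparability between patches. A constant volume maps to
   zero. Per-stack normalisation is what neutralises the bright-outlier
   acquisition.
5. **Patchify** — non-overlapping 32³ tiles in lexicographic (z, y, x)
   grid order. `reassemble` inverts the tiling, strips the padding and
   places the ROI back at its offset in a zero background, bit-exactly;
   this round trip is property-tested over randomised geometries.

Geometry (original shape, bounding box, pad) is serialised to a JSON
sidecar so predictions can be mapped back without reloading the mask.

## Network

A shallow two-level 3D U-Net: one encoder level, a 2× max-pool, a
bottleneck, 2× upsampling with a skip concatenation, one decoder level,
and a 1³ convolution + sigmoid head. Every convolution is 3×3×3, stride
1, zero same-padding (output shape must equal input shape for
reassembly), each followed by batch normalisation and ReLU; two
convolutions per level.

**Layer widths.** The published description fixes kernel, stride, depth,
normalisation, activations and a total of 831,105 trainable parameters,
but not the widths. `enumerate_configs_matching` enumerates the width
space (encoder 1–256, bottleneck 1–512, decoder solved in closed form,
1–3 convs per block, nearest vs transposed-conv upsampling, 1³/3³ head)
against that budget. No configuration with strict channel doubling
matches the printed total under any batch-norm counting convention, so
the budget itself pins the widths only up to a family; among exact
matches we fix the reference by preferring the structure the description
states (two convs per block, batch norm, a parameter-free upsampling
step, 1³ head) and then minimal relative deviation from the conventional
double-then-halve width pattern. That yields **encoder 80 / bottleneck
91 / decoder 41**, whose trainable-parameter count (convolution weights
and biases plus batch-norm scale/shift; running statistics excluded) is
exactly 831,105.

**Implementation.** The layers (3D convolution via im2col, batch norm,
max-pool, nearest upsampling, transposed convolution, sigmoid) are
implemented directly on numpy arrays with explicit forward/backward
passes and an Adam optimiser. At this scale (<1 M parameters, 32³
patches) CPU matrix multiplication is entirely adequate, and the
backward pass is verified against float64 central differences in the
test suite.

**Head initialisation.** The head bias starts at −log((1−π)/π) with
π = 0.01, the standard prior-probability initialisation for focal-loss
training under extreme imbalance: the network begins by predicting the
background prior everywhere instead of 0.5, so early gradients
concentrate on vessel voxels rather than on uniformly pushing the
background down.

## Training

* **Loss** — binary focal loss, γ = 2, no α class weight:
  mean of −[y(1−p)^γ log p + (1−y) p^γ log(1−p)], p clipped to
  [1e−7, 1−1e−7]. γ = 0 reduces to binary cross-entropy (tested to
  1e−9).
* **Augmentation** — independently with probability 0.5 each: a random
  flip along x, y or both (applied identically to image and label), a
  single per-patch brightness shift ~ N(0, 0.1), voxelwise noise
  ~ N(0, 0.05); the image is re-clipped to [0, 1]. Labels are only ever
  flipped, so they stay binary.
* **Optimiser / schedule** — Adam, learning rate 1e−4, up to 100
  epochs, early stopping on validation loss with patience 30 and
  minimum improvement 1e−4, best-validation weights restored.
* **Split** — a uniform 80/20 split at patch level pooled over the
  training stacks; the 20 % partition is the early-stopping monitor.
  (Whether that partition is a monitor or a held-out patch test set is
  ambiguous in the source; the monitor reading is implemented, since
  held-out stacks provide the actual evaluation.)
* **Imbalance handling** — empty-label patches are kept; the focal loss
  is the sole imbalance mechanism. Batch size defaults to 16 (never
  printed). All randomness (init, split, augmentation) flows from one
  seed.
* **Evaluation** — leave-one-out over stacks: train on N−1, predict the
  held-out stack, apply each post-processing setting, score against the
  ground truth inside the brain mask. Training sets carry stack
  provenance tags and are asserted never to contain held-out patches.

## Post-processing

Two binarisations of the reassembled probability map:

* **Threshold** — foreground iff p ≥ t (inclusive, so region growing
  with s = t degenerates exactly to thresholding).
* **Region growing** — seeds {p ≥ s} grown through {p ≥ t}, t ≤ s,
  computed as the union of connected components of {p ≥ t} that contain
  a seed (equivalent to breadth-first growth, and tested against an
  explicit per-component oracle). Default connectivity is 6 (face
  neighbours; conservative for thin vessels), 26 available.

Both support a per-patch scope (growth cannot cross patch seams) besides
the default full-volume scope; the two differ in whether post-processing
runs inside or after the patch loop, a discrepancy in the source
description that is surfaced as an option rather than silently resolved.

## Vesselness baseline

Multiscale Frangi filter on the identically pre-processed volume (patch
step skipped), α = β = 0.5, structureness parameter set per scale to
half the maximum Frobenius norm of the Hessian, dark ridges, maximum
response over scales, then a per-stack threshold (0.02–0.03). Scales
default to **1.0, 1.5, 2.0 voxels**: the filter's minimum useful scale
is the smallest vessel radius; a 0.5-voxel scale sits below the σ = 0.5
pre-blur and responds mostly to voxel noise (on phantoms it raised the
tissue false-positive rate from ~0.05 % to several percent, far from
the published confusion rows). The skimage implementation provides the
filter; thresholds are configuration values, not auto-selected.

## Synthetic phantoms

`phantom.generate_phantom` emulates the dataset's statistical structure:
an ellipsoidal bright "brain" (mean tissue intensity 11,000 on the
uint16 scale, matching typical stack means) inside a darker surround;
vessel trees as branching momentum random walks rasterised as tubes
(radii 0.5–2.0 voxels — the real radius distribution is unpublished,
this range covers sub-voxel capillaries to small arteries at ~50 μm
voxels); vessels darkened to 25 % of local tissue brightness; a smooth
multiplicative brightness drift (amplitude 0.15); additive Gaussian
noise (σ = 5 % of tissue mean, i.e. tissue SNR ≈ 20, plausible for a
56-average FISP acquisition); empty first/last 3 % of slices;
quantisation to uint16. Trees are added segment by segment until the
vessel fraction inside the brain reaches the configured target
(default 0.12 %, inside the observed 0.036–0.134 % range), which keeps
the achieved fraction within the ±30 % contract even in small test
volumes. Identical seeds give bit-identical phantoms.

**What phantoms do not capture:** MRI physics (no Rician noise floor,
no partial-volume point-spread, no FISP banding), anatomy (no cavities
or ventricles — the main source of dark non-vessel structures in real
data), vessel tortuosity/hierarchy statistics, and annotation noise in
the ground truth. Passing the phantom suite therefore establishes that
the pipeline's machinery is correct and that the learned model can
exploit dark-tube contrast; it does not establish real-data Dice
levels, which depend on those unmodelled factors.

## Scaled-down end-to-end experiment

The acceptance experiment trains a narrow-width variant of the same
topology (4/8/4 filters) on three 64³ phantoms (24 patches) and
evaluates the fourth, with the Frangi baseline at threshold 0.02 as
comparator. Problem sizes are chosen so the whole experiment runs in
minutes on one CPU. Three training constants are adapted to the short
schedule and documented here as the experiment's own choices: the
augmentation enlargement factor (8 copies per patch per epoch), batch
size 2, and learning rate 1e−2 instead of 1e−4. The full-scale recipe
implies tens of thousands of Adam steps, whereas ten epochs over 24
patches give ~10³; since Adam's per-parameter displacement is bounded
by (steps × learning rate), the full-scale rate cannot train *any*
correct implementation in this regime — the sigmoid logit on vessel
voxels has to travel ≈5 units from its prior initialisation — so the
product steps × lr is kept comparable instead. Early stopping's
best-weight restoration is disabled here: at this scale the 20 %
validation partition frequently contains zero vessel voxels, making
its loss blind to the quantity being learned. The acceptance
thresholds themselves (held-out Dice ≥ 0.5, U-Net above the baseline)
are fixed, not adapted.

## Numerical choices and degenerate inputs

* Min–max normalisation of a constant volume returns zeros.
* Probabilities are clipped at 1e−7 from both ends inside the loss.
* Max-pool ties resolve to the first maximum (argmax convention);
  gradient flows to exactly one voxel per window.
* Batch-norm uses ε = 1e−5 and momentum 0.9 running statistics;
  inference always uses running statistics, making it deterministic.
* Empty brain masks, non-divisible patch shapes, t > s threshold pairs
  and rank ≠ 3 files raise immediately with specific messages.
* Masks load as {0, 1} uint8; more than two distinct values trigger a
  warning before binarisation.

## Known limitations

* The reference widths are one member of the family consistent with the
  printed parameter budget; other exact matches exist and are
  enumerable with `enumerate_configs_matching`.
* Training at full scale (eight 400×400×320 stacks, 100 epochs) is
  outside the scope of this package's tests; the numpy implementation
  is CPU-bound and intended for desk-scale experiments and method
  validation, not production-scale training.
* No morphological cleanup or minimum-component filtering is applied
  after binarisation; the original workflow's manual mask curation is
  likewise out of scope.
* Overlapping-patch tiling with blending and anisotropic voxels are not
  supported.
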