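# murivess

Fully automatic segmentation of blood vessels in micro-MRI (μMRI) stacks
of murine brains, for preclinical imaging groups that have only a
handful of annotated stacks. Vessels appear as dark tubular structures
occupying well under 1 % of the brain volume, so the package combines a
patch-based shallow 3D U-Net trained with binary focal loss against the
extreme class imbalance, threshold / seeded region-growing
post-processing, a multiscale Frangi vesselness baseline, and
confusion-matrix / Dice evaluation under leave-one-out
cross-validation. A synthetic vascular phantom generator reproduces the
statistical structure of real acquisitions (uint16 intensities, dark
vessels at 0.036–0.134 % foreground, per-stack brightness variation,
empty boundary slices) so the entire pipeline is testable without
animal data.

## The model

Stacks are cropped to the brain mask, zero-padded to multiples of 32,
blurred (Gaussian, σ = 0.5), min–max normalised per stack and tiled
into non-overlapping 32³ patches. The network is a shallow two-level
3D U-Net — encoder level, 2× max-pool, bottleneck, 2× upsampling with
skip concatenation, decoder level, 1³ sigmoid head; all convolutions
3×3×3 stride 1 with batch norm + ReLU; **831,105 trainable
parameters** (reference widths 80/91/41, fixed by exhaustive
enumeration against that budget). Training uses the focal loss

    FL(p, y) = −[ y (1−p)^γ log p + (1−y) p^γ log(1−p) ],   γ = 2,

Adam (lr 1e−4), flip/brightness/noise augmentation, an 80/20 patch
split and early stopping (patience 30, min Δ 1e−4). Reassembled
probability maps are binarised by a plain threshold t or by region
growing from seeds {p ≥ s} through {p ≥ t}. Segmentations are scored
by accuracy, recall, precision and Dice (DSC = 2TP/(2TP+FP+FN)) inside
the brain mask. The implementation of the network is pure
numpy (explicit forward/backward passes, gradient-checked), which is
entirely adequate at this parameter count.

## Worked example

```python
import numpy as np
from murivess import phantom, preprocess, postprocess, evaluate, baseline
from murivess.nn import unet

# a synthetic 64^3 stack: uint16 intensities, brain mask, vessel ground truth
p = phantom.generate_phantom(phantom.PhantomConfig(shape=(64, 64, 64), seed=1))
print(f"vessel fraction in brain: {p.fg_fraction:.4%}")

# reference architecture and its parameter budget
model = unet.build_unet(unet.REFERENCE_CONFIG, seed=0)
print("trainable parameters:", unet.count_parameters(model))

# Frangi vesselness baseline with the shared pre-processing
seg = baseline.vesselness_segment(p.intensity, p.brain_mask,
                                  baseline.VesselnessConfig(threshold=0.02))
m = evaluate.compute_metrics(
    evaluate.confusion_counts(seg, p.vessel_gt, p.brain_mask))
print(f"baseline Dice {m.dsc:.3f}, recall {m.recall:.3f}, precision {m.precision:.3f}")
```

prints

```
vessel fraction in brain: 0.1264%
trainable parameters: 831105
baseline Dice 0.539, recall 1.000, precision 0.369
```

— the phantom hits its configured vessel fraction (target 0.12 %,
±30 % contract), the reference U-Net matches its printed parameter
budget exactly, and on a clean high-contrast phantom the vesselness
filter finds every vessel voxel (recall 1.0) but over-segments around
the thin tubes (precision 0.37), the classical filter's familiar
failure mode that motivates the learned model.

A command-line interface covers the same stages end to end:

```bash
murivess phantom --out data/p0 --seed 0
murivess preprocess data/p0/intensity.tif data/p0/brain_mask.tif --out work/
murivess baseline data/p0/intensity.tif data/p0/brain_mask.tif --out work/ --threshold 0.02
murivess evaluate work/segmentation.tif data/p0/vessels_gt.tif data/p0/brain_mask.tif
murivess summary   # layer configuration + parameter count
```

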