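"""Training of the patch-based vessel segmentation model.

The recipe: random flip / brightness / noise augmentation of 32-cubed
patches, binary focal loss (gamma = 2) against the extreme
foreground-background imbalance (vessels are well under 1 % of brain
voxels), Adam at learning rate 1e-4, an 80/20 patch-level split whose
20 % partition monitors early stopping (patience 30 epochs, minimum
improvement 1e-4, best-validation weights restored), and leave-one-out
cross-validation over stacks for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from murivess import evaluate as ev
from murivess import postprocess as pp
from murivess import preprocess as pre
from murivess.nn.unet import UNet3D, UNetConfig, build_unet, predict_patches

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "augment",
    "focal_loss",
    "focal_loss_grad",
    "split_patches",
    "early_stopping_epoch",
    "train_model",
    "run_loocv",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    patience: int = 30
    min_delta: float = 1e-4
    learning_rate: float = 1e-4
    gamma: float = 2.0
    split_ratio: float = 0.8
    batch_size: int = 16
    augment_copies: int = 1  # training-set enlargement factor per epoch
    restore_best: bool = True  # keep the best-validation-loss weights
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass(frozen=True)
class AugmentConfig:
    """Random patch augmentation: flips plus intensity perturbations.

    Each transform is applied independently with probability ``prob``;
    the flip axis is drawn uniformly from x, y or both.  The brightness
    shift is a single Normal(0, ``brightness_sigma``) scalar per patch
    and the noise is voxelwise Normal(0, ``noise_sigma``); both touch
    only the image, which is re-clipped to [0, 1].
    """

    brightness_sigma: float = 0.1
    noise_sigma: float = 0.05
    prob: float = 0.5

    def __post_init__(self):
        if self.brightness_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")


def augment(image, label, config: AugmentConfig, rng: np.random.Generator):
    """Apply flips identically to image and label, intensity jitter to image."""
    image = np.asarray(image, dtype=np.float32)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ValueError("image and label shapes must match")
    if rng.random() < config.prob:
        axes = ((2,), (1,), (1, 2))[rng.integers(3)]  # x, y, or both (z is the slice axis)
        image = np.flip(image, axis=axes)
        label = np.flip(label, axis=axes)
    if rng.random() < config.prob:
        image = image + rng.normal(0.0, config.brightness_sigma)
    if rng.random() < config.prob:
        image = image + rng.normal(0.0, config.noise_sigma, image.shape).astype(np.float32)
    return np.clip(image, 0.0, 1.0).astype(np.float32), np.ascontiguousarray(label)


def focal_loss(pred: np.ndarray, target: np.ndarray, gamma: float = 2.0) -> float:
    """Mean binary focal loss; ``gamma=0`` is binary cross-entropy.

    ``-[y (1-p)^g log p + (1-y) p^g log(1-p)]`` averaged over voxels,
    with no class-balancing weight.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1 - _EPS)
    y = np.asarray(target, dtype=np.float64)
    loss = -(y * (1 - p) ** gamma * np.log(p) + (1 - y) * p**gamma * np.log(1 - p))
    return float(loss.mean())


def focal_loss_grad(pred: np.ndarray, target: np.ndarray, gamma: float = 2.0) -> np.ndarray:
    """d(mean focal loss)/d(pred), for backpropagation."""
    p = np.clip(np.asarray(pred, dtype=np.float32), _EPS, 1 - _EPS)
    y = np.asarray(target, dtype=np.float32)
    if gamma == 0:
        g = -y / p + (1 - y) / (1 - p)
    else:
        g = y * (gamma * (1 - p) ** (gamma - 1) * np.log(p) - (1 - p) ** gamma / p) + (
            1 - y
        ) * (-gamma * p ** (gamma - 1) * np.log(1 - p) + p**gamma / (1 - p))
    return (g / p.size).astype(np.float32)


def split_patches(patches, ratio: float = 0.8, seed: int = 0):
    """Uniform random disjoint split at patch level; sizes round(r*n) / rest."""
    n = len(patches)
    if n < 5:
        raise ValueError("need at least 5 patches to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(ratio * n))
    train_idx = order[:n_train]
    val_idx = order[n_train:]
    return [patches[i] for i in train_idx], [patches[i] for i in val_idx]


def early_stopping_epoch(val_losses, patience: int, min_delta: float) -> int:
    """1-based epoch at which training stops for a given loss history.

    An epoch counts as non-improving when it beats the best loss so far
    by no more than ``min_delta``; after ``patience`` consecutive
    non-improving epochs training stops.  Returns ``len(val_losses)``
    when the criterion never fires.
    """
    best = np.inf
    bad = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if best - loss > min_delta:
            best = loss
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                return epoch
    return len(val_losses)


def _batches(items, size):
    for i in range(0, len(items), size):
        yield items[i : i + size]


def _epoch_loss(model, patches, gamma, batch_size):
    model.eval()
    total, n = 0.0, 0
    for batch in _batches(patches, batch_size):
        x = np.stack([b[0] for b in batch])[:, None]
        y = np.stack([b[1] for b in batch])[:, None]
        p = model.forward(x)
        total += focal_loss(p, y, gamma) * len(batch)
        n += len(batch)
    return total / n


def train_model(
    model: UNet3D,
    train,
    val,
    config: TrainConfig = TrainConfig(),
    augment_config: AugmentConfig = AugmentConfig(),
):
    """Train with Adam + focal loss + early stopping; returns (model, history).

    ``train`` and ``val`` are sequences of ``(image_patch, label_patch)``
    pairs in [0, 1] / {0, 1}.  With ``config.restore_best`` (the
    default) the best-validation-loss weights are restored before
    returning.  ``history`` is a list of dicts with epoch, training
    loss and validation loss.
    """
    if not train or not val:
        raise ValueError("train and val must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(lr=config.learning_rate)
    history = []
    best_loss = np.inf
    best_state = model.state_dict() if config.restore_best else None
    bad = 0

    for epoch in range(1, config.max_epochs + 1):
        samples = []
        for img, lab in train:
            for _ in range(config.augment_copies):
                samples.append(augment(img, lab, augment_config, rng))
        rng.shuffle(samples)

        model.train()
        train_loss, n_seen = 0.0, 0
        for batch in _batches(samples, config.batch_size):
            x = np.stack([b[0] for b in batch])[:, None]
            y = np.stack([b[1] for b in batch])[:, None].astype(np.float32)
            opt.zero_grad()
            p = model.forward(x)
            loss = focal_loss(p, y, config.gamma)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            model.backward(focal_loss_grad(p, y, config.gamma))
            opt.step()
            train_loss += loss * len(batch)
            n_seen += len(batch)

        val_loss = _epoch_loss(model, val, config.gamma, config.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": train_loss / n_seen, "val_loss": val_loss}
        )
        if best_loss - val_loss > config.min_delta:
            best_loss = val_loss
            if config.restore_best:
                best_state = model.state_dict()
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break

    if config.restore_best:
        model.load_state_dict(best_state)
    return model, history


def labeled_patches(volume, brain_mask, vessel_gt, preprocess_config=pre.PreprocessConfig()):
    """Preprocess one stack into aligned (image, label) patch pairs.

    The intensity volume runs through the full chain; the ground truth
    runs through the same geometric steps only (crop, pad, patchify), so
    patch ``i`` of both tilings covers the same voxels.
    """
    img_patches = pre.preprocess_stack(volume, brain_mask, preprocess_config)
    gt_roi, geom = pre.extract_roi(vessel_gt, brain_mask)
    gt_roi, geom = pre.pad_to_block(gt_roi, geom, preprocess_config.block)
    gt_patches = pre.patchify(gt_roi, geom, preprocess_config.block)
    pairs = [
        (img, (gt > 0).astype(np.float32))
        for img, gt in zip(img_patches.patches, gt_patches.patches)
    ]
    return pairs, img_patches


def run_loocv(
    stacks,
    train_config: TrainConfig = TrainConfig(),
    preprocess_config: pre.PreprocessConfig = pre.PreprocessConfig(),
    postprocess_grid=(pp.PostprocessConfig(mode="threshold", t=0.45),),
    unet_config: UNetConfig = None,
    seed: int = 0,
):
    """Leave-one-out cross-validation over stacks.

    ``stacks`` is a sequence of ``(volume, brain_mask, vessel_gt)``.  For
    each fold the model trains on the pooled patches of all other stacks
    (with the 80/20 split internal to them), predicts the held-out
    stack, applies every post-processing setting in the grid and scores
    against the ground truth inside the brain mask.  Returns a list of
    row dicts (fold x setting) plus per-setting averages.
    """
    if len(stacks) < 2:
        raise ValueError("leave-one-out needs at least 2 stacks")
    if unet_config is None:
        from murivess.nn.unet import REFERENCE_CONFIG

        unet_config = REFERENCE_CONFIG

    rows = []
    for fold, held_out in enumerate(stacks):
        pool = []
        for j, stack in enumerate(stacks):
            if j == fold:
                continue
            pairs, _ = labeled_patches(*stack, preprocess_config)
            pool.extend((img, lab, j) for img, lab in pairs)
        assert all(tag != fold for *_, tag in pool), "held-out stack leaked into training"
        train_set, val_set = split_patches(pool, train_config.split_ratio, seed=seed + fold)
        train_set = [(img, lab) for img, lab, _ in train_set]
        val_set = [(img, lab) for img, lab, _ in val_set]

        model = build_unet(unet_config, seed=seed + fold)
        model, history = train_model(model, train_set, val_set, train_config)

        volume, brain_mask, vessel_gt = held_out
        patchset = pre.preprocess_stack(volume, brain_mask, preprocess_config)
        prob_patches = predict_patches(model, patchset)
        prob = pre.reassemble(prob_patches)

        for setting in postprocess_grid:
            if setting.scope == "per_patch":
                seg = pre.reassemble(pp.postprocess_patches(prob_patches, setting))
            else:
                seg = pp.postprocess_probabilities(prob, setting)
            counts = ev.confusion_counts(seg, vessel_gt, brain_mask)
            metrics = ev.compute_metrics(counts)
            rows.append(
                {
                    "fold": fold,
                    "setting": _setting_name(setting),
                    "epochs_run": len(history),
                    **metrics.as_dict(),
                }
            )

    averages = {}
    for setting in postprocess_grid:
        name = _setting_name(setting)
        per_fold = [
            ev.Metrics(r["accuracy"], r["recall"], r["precision"], r["dsc"])
            for r in rows
            if r["setting"] == name
        ]
        averages[name] = ev.aggregate(per_fold)
    return rows, averages


def _setting_name(cfg: pp.PostprocessConfig) -> str:
    if cfg.mode == "threshold":
        return f"threshold t={cfg.t}"
    return f"region_growing s={cfg.s} t={cfg.t}"
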