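"""Training loop, cross-validation split, prediction and resizing utilities.

The optimizer recipe: Adam with weight decay 1e-5, base learning rate 0.01
decayed by 0.95 per epoch, batch size 8, 150 epochs, soft dice loss on
sigmoid outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .metrics import BinaryMask, dsc, evaluate_dataset, soft_dice_loss
from .network import CFANet, NetworkConfig, load_checkpoint, save_checkpoint
from .nn import functional as F
from .nn.autograd import Tensor
from .nn.optim import Adam
from .synthetic import SamplePair

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "lr_schedule", "kfold_split", "train", "predict",
    "resize_pair", "cross_validate", "load_nifti_slices",
]


def load_nifti_slices(path) -> list[np.ndarray]:
    """Load a NIfTI volume as 2-D slices along the last axis, scaled to [0,1]."""
    import nibabel as nib  # optional dependency, only needed for NIfTI input

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {vol.shape}")
    lo, hi = float(vol.min()), float(vol.max())
    if hi > lo:
        vol = (vol - lo) / (hi - lo)
    return [vol[:, :, k] for k in range(vol.shape[2])]


@dataclass
class TrainConfig:
    base_lr: float = 0.01
    decline_rate: float = 0.95
    batch_size: int = 8
    epochs: int = 150
    weight_decay: float = 1e-5
    smooth: float = 1.0
    seed: int = 0
    folds: int = 5

    def __post_init__(self):
        if not 0.0 < self.base_lr <= 1.0:
            raise ValueError(f"base_lr must be in (0, 1], got {self.base_lr}")
        if not 0.0 < self.decline_rate <= 1.0:
            raise ValueError(f"decline_rate must be in (0, 1], got {self.decline_rate}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Exponentially decayed learning rate ``base_lr * decline_rate**epoch``."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return config.base_lr * config.decline_rate**epoch


def kfold_split(n_items: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Shuffle indices into ``k`` disjoint folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if k > n_items:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    perm = np.random.default_rng(seed).permutation(n_items)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _to_batch(samples: Sequence[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, 3, H, W) images and (N, 1, H, W) masks."""
    images, masks = [], []
    for s in samples:
        img = np.asarray(s.image, dtype=np.float32)
        if img.ndim == 2:
            img = np.repeat(img[None], 3, axis=0)  # grayscale -> RGB stem
        elif img.ndim == 3 and img.shape[2] in (1, 3):
            img = np.moveaxis(img, 2, 0)
            if img.shape[0] == 1:
                img = np.repeat(img, 3, axis=0)
        images.append(img)
        masks.append(np.asarray(s.mask, dtype=np.float32)[None])
    return np.stack(images), np.stack(masks)


def train(
    train_config: TrainConfig,
    network_config: NetworkConfig,
    data: Sequence[SamplePair],
    checkpoint_path=None,
    log_path=None,
) -> tuple[CFANet, pd.DataFrame]:
    """Fit the network on ``data``; returns the model and the per-epoch log.

    The log has one row per epoch: epoch, lr, loss, train_dsc (computed from
    the thresholded training-mode outputs seen during that epoch).
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    images, masks = _to_batch(data)
    if images.shape[2] % 32 or images.shape[3] % 32:
        raise ValueError(
            f"training images must have dims divisible by 32, got {images.shape[2:]}"
        )
    model = CFANet(network_config)
    model.train()
    opt = Adam(model.parameters(), lr=train_config.base_lr,
               weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    n = len(data)
    bs = train_config.batch_size
    rows = []
    for epoch in range(train_config.epochs):
        lr = lr_schedule(epoch, train_config)
        opt.lr = lr
        order = rng.permutation(n)
        losses, dscs = [], []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb = Tensor(images[idx])
            yb = masks[idx]
            probs = F.sigmoid(model(xb))
            loss = soft_dice_loss(probs, yb, smooth=train_config.smooth)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss {loss_val} at epoch {epoch}, "
                    f"batch starting {start}; aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss_val)
            pred_bin = probs.data >= 0.5
            for p, t in zip(pred_bin, yb):
                dscs.append(dsc(p[0].astype(np.uint8), t[0].astype(np.uint8)))
        rows.append({
            "epoch": epoch,
            "lr": lr,
            "loss": float(np.mean(losses)),
            "train_dsc": float(np.mean(dscs)),
        })
        logger.info("epoch %d  lr %.5f  loss %.4f  dsc %.4f",
                    epoch, lr, rows[-1]["loss"], rows[-1]["train_dsc"])
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model, extra={
            "train_config": vars(train_config).copy(),
            "final_epoch": int(train_config.epochs - 1),
            "final_loss": rows[-1]["loss"],
        })
    return model, log


def predict(model_or_checkpoint, images, threshold: float = 0.5,
            batch_size: int = 8) -> list[np.ndarray]:
    """Threshold sigmoid outputs into binary masks (rule: prob >= threshold).

    Note the boundary convention: an exactly-zero logit has probability 0.5
    and is classified as foreground at the default threshold.
    """
    if isinstance(model_or_checkpoint, CFANet):
        model = model_or_checkpoint
    else:
        model, _ = load_checkpoint(model_or_checkpoint)
    samples = [
        img if isinstance(img, SamplePair)
        else SamplePair(image=np.asarray(img),
                        mask=np.zeros(np.asarray(img).shape[:2], np.uint8))
        for img in images
    ]
    xb, _ = _to_batch(samples)
    if xb.shape[1] != model.config.input_channels:
        raise ValueError(
            f"checkpoint expects {model.config.input_channels} input channels, "
            f"got {xb.shape[1]}"
        )
    out: list[np.ndarray] = []
    for start in range(0, len(xb), batch_size):
        probs = model.predict_proba(xb[start:start + batch_size])
        out.extend((p[0] >= threshold).astype(np.uint8) for p in probs)
    return out


def resize_pair(sample: SamplePair, target_size: int | tuple[int, int]) -> SamplePair:
    """Resize image (bilinear) and mask (nearest, stays binary)."""
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    th, tw = target_size
    if th % 32 or tw % 32:
        raise ValueError(f"target size {target_size} must be divisible by 32")
    if sample.image.shape[:2] == (th, tw):
        return SamplePair(image=sample.image.copy(), mask=sample.mask.copy(),
                          spacing=sample.spacing)
    img = np.asarray(
        Image.fromarray(np.asarray(sample.image, dtype=np.float32), mode="F")
        .resize((tw, th), Image.BILINEAR),
        dtype=np.float32,
    )
    mask = np.asarray(
        Image.fromarray(sample.mask.astype(np.uint8)).resize((tw, th), Image.NEAREST)
    )
    sy = sample.spacing[0] * sample.image.shape[0] / th
    sx = sample.spacing[1] * sample.image.shape[1] / tw
    return SamplePair(image=img, mask=mask, spacing=(sy, sx))


def cross_validate(
    train_config: TrainConfig,
    network_config: NetworkConfig,
    data: Sequence[SamplePair],
) -> pd.DataFrame:
    """k-fold cross-validation; returns per-fold mean DSC/HD."""
    folds = kfold_split(len(data), train_config.folds, train_config.seed)
    rows = []
    for fi, test_idx in enumerate(folds):
        test_set = [data[i] for i in test_idx]
        train_set = [data[i] for i in range(len(data)) if i not in set(test_idx.tolist())]
        model, _ = train(train_config, network_config, train_set)
        preds = predict(model, test_set)
        report = evaluate_dataset(
            preds, [s.mask for s in test_set],
            case_ids=[f"fold{fi}_case{i}" for i in range(len(test_set))],
        )
        rows.append({
            "fold": fi,
            "n_test": len(test_set),
            "mean_dsc": report.mean_dsc,
            "mean_hd": report.mean_hd,
            "n_excluded_from_hd": report.n_excluded_from_hd,
        })
    return pd.DataFrame(rows)
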