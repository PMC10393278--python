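"""Seeded CPU training loop and evaluation for the segmentation network.

Training minimizes the soft Dice loss with Adam on mini-batches drawn by a
seeded shuffle, tracks per-epoch train/val loss and validation Dice/mIoU,
and keeps the checkpoint with the best validation Dice.  Everything is
deterministic for a fixed seed on CPU.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .area import binarize
from .metrics import ConfusionCounts, MetricsReport, compute_metrics, confusion
from .nn import Adam, Tensor, dice_coefficient, dice_loss, no_grad
from .nn.unet import UNet


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 4
    #: Adam step size.  With the soft-Dice objective, 1e-3 can drive the
    #: softmax into an all-background absorbing state; 3e-4 is stable.
    learning_rate: float = 3e-4
    seed: int = 0
    device: str = "cpu"
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.device != "cpu":
            raise ValueError("only cpu training is supported")


class ConfigurationError(RuntimeError):
    pass


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class LoadedSplit:
    """In-memory image/mask arrays for one manifest split."""
    images: np.ndarray   # N x 3 x H x W float32 in [0, 1]
    masks: np.ndarray    # N x H x W float32 {0, 1}
    true_areas: np.ndarray
    paths: list[str]


def load_split(manifest: pd.DataFrame, root, split: str) -> LoadedSplit:
    rows = manifest[manifest["split"] == split]
    root = Path(root)
    images, masks, paths = [], [], []
    missing = []
    for _, row in rows.iterrows():
        ip, mp = root / row["image"], root / row["mask"]
        if not ip.exists() or not mp.exists():
            missing.append(str(ip if not ip.exists() else mp))
            continue
        images.append(sio.read_image(ip).astype(np.float32).transpose(2, 0, 1) / 255.0)
        masks.append(sio.read_mask(mp).astype(np.float32))
        paths.append(str(ip))
    if missing:
        raise FileNotFoundError(f"missing dataset files: {missing}")
    return LoadedSplit(
        images=np.stack(images) if images else np.empty((0,)),
        masks=np.stack(masks) if masks else np.empty((0,)),
        true_areas=rows["true_area_mm2"].to_numpy(dtype=float),
        paths=paths,
    )


def _leaf_channel(probs: Tensor) -> Tensor:
    """Extract the foreground channel of an (N, 2, H, W) softmax output."""
    data = probs.data[:, 1]

    def bwd(g, a=probs):
        full = np.zeros_like(a.data)
        full[:, 1] = g
        a._accum(full)

    return Tensor(data, parents=(probs,), backward=bwd)


def train(model: UNet, manifest: pd.DataFrame, config: TrainConfig,
          dataset_root=".", val_metrics_every: int = 1,
          progress=None) -> dict:
    """Train ``model`` in place; return the per-epoch history dict.

    History keys: ``train_loss``, ``val_loss``, ``val_dice``, ``val_miou``
    (lists, one entry per epoch).  The best-validation-Dice parameters are
    restored into the model at the end and written to
    ``config.checkpoint_path`` when set.
    """
    train_split = load_split(manifest, dataset_root, "train")
    val_split = load_split(manifest, dataset_root, "val")
    if len(train_split.paths) == 0 or len(val_split.paths) == 0:
        raise ConfigurationError("train and val splits must be nonempty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_dice": [], "val_miou": []}
    best_dice, best_state = -1.0, None
    n = len(train_split.paths)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = train_split.images[idx]
            yb = train_split.masks[idx]
            model.zero_grad()
            loss = dice_loss(_leaf_channel(model.forward(xb)), yb)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss, val_dice, val_miou = _validate(model, val_split)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_dice"].append(val_dice)
        history["val_miou"].append(val_miou)
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = [a.copy() for a in model.state_arrays()]
        if progress is not None:
            progress(epoch, history)

    if best_state is not None:
        model.load_state_arrays(best_state)
    if config.checkpoint_path:
        sio.save_checkpoint(config.checkpoint_path, model)
    return history


def _validate(model: UNet, split: LoadedSplit) -> tuple[float, float, float]:
    losses, dices = [], []
    counts = ConfusionCounts(0, 0, 0, 0)
    with no_grad():
        for i in range(len(split.paths)):
            probs = model.forward(split.images[i:i + 1])
            leaf = probs.data[0, 1]
            losses.append(float(dice_loss(Tensor(leaf), split.masks[i]).data))
            pred = binarize(leaf)
            dices.append(dice_coefficient(pred, split.masks[i]))
            counts = counts + confusion(pred, split.masks[i])
    miou = compute_metrics(counts).miou
    return float(np.mean(losses)), float(np.mean(dices)), float(miou)


def evaluate(model, manifest: pd.DataFrame, dataset_root=".",
             split: str = "test", threshold: float = 0.5) -> MetricsReport:
    """Micro-averaged metrics over one split: confusion counts are summed
    over all images before any ratio is taken.  Mean per-image inference
    time is attached as informational output."""
    data = load_split(manifest, dataset_root, split)
    if len(data.paths) == 0:
        raise ConfigurationError(f"split {split!r} is empty")
    counts = ConfusionCounts(0, 0, 0, 0)
    t0 = time.perf_counter()
    for i in range(len(data.paths)):
        img = (data.images[i].transpose(1, 2, 0) * 255.0).astype(np.uint8)
        prob = model.predict_proba(img)
        counts = counts + confusion(binarize(prob, threshold), data.masks[i])
    per_image = (time.perf_counter() - t0) / len(data.paths)
    return compute_metrics(counts, inference_seconds_per_image=per_image)
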