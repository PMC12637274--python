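"""Training loop, callback state machines, prediction and evaluation.

The training protocol: Adam (initial learning rate 1e-4) with global-norm
gradient clipping at 1.0, batch size 1, composite Dice + categorical
cross-entropy loss on softmaxed logits, epoch-level callbacks —
reduce-on-plateau (halve the learning rate after 15 epochs without
validation-loss improvement, floor 1e-15), early stopping (halt after 35
stagnant epochs, restoring the best weights) and best-checkpoint keeping.
"Improvement" means a strict decrease of the monitored validation loss.

Both callback state machines are pure functions of the validation-loss
trace, so they are testable against brute-force references independent of
any model.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Adam
from .losses import composite_loss, one_hot
from .metrics import overlap_metrics
from .network import SegmentationModel
from .synthio import SamplePair

__all__ = [
    "TrainConfig",
    "TrainState",
    "plateau_step",
    "early_stop_step",
    "train",
    "predict",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (full-scale defaults; tests use desk-scale overrides)."""

    epochs: int = 600
    steps_per_epoch: int = 1000
    validation_steps: int = 200
    batch_size: int = 1
    learning_rate: float = 1e-4
    clipnorm: float = 1.0
    plateau_factor: float = 0.5
    plateau_patience: int = 15
    min_lr: float = 1e-15
    early_stop_patience: int = 35
    restore_best: bool = True
    dice_weight: float = 1.0
    cce_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau factor must be in (0, 1)")
        if self.plateau_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patience values must be positive")


@dataclass
class TrainState:
    """Mutable training state: learning rate, callback counters, history."""

    current_lr: float
    best_val_loss: float = np.inf
    best_epoch: int = -1
    plateau_best: float = np.inf
    plateau_counter: int = 0
    stop_best: float = np.inf
    stop_counter: int = 0
    stopped: bool = False
    epoch: int = 0
    history: list[dict] = field(default_factory=list)


def plateau_step(
    state: TrainState,
    val_loss: float,
    factor: float = 0.5,
    patience: int = 15,
    min_lr: float = 1e-15,
) -> TrainState:
    """Reduce-on-plateau: halve the learning rate after `patience` stagnant epochs.

    A strict decrease of ``val_loss`` below the best seen resets the counter;
    otherwise the counter increments and, on reaching ``patience``, the
    learning rate is multiplied by ``factor`` (never below ``min_lr``) and
    the counter resets.
    """
    if val_loss < state.plateau_best:
        state.plateau_best = val_loss
        state.plateau_counter = 0
    else:
        state.plateau_counter += 1
        if state.plateau_counter >= patience:
            state.current_lr = max(state.current_lr * factor, min_lr)
            state.plateau_counter = 0
    return state


def early_stop_step(state: TrainState, val_loss: float, patience: int = 35) -> TrainState:
    """Early stopping: set ``stopped`` after `patience` epochs without improvement."""
    if val_loss < state.stop_best:
        state.stop_best = val_loss
        state.stop_counter = 0
    else:
        state.stop_counter += 1
        if state.stop_counter >= patience:
            state.stopped = True
    return state


def _batches(pairs: list[SamplePair], batch_size: int, order: np.ndarray):
    """Yield (images, masks) arrays for index order, cycling if needed by caller."""
    for start in range(0, len(order) - batch_size + 1, batch_size):
        ids = order[start : start + batch_size]
        imgs = np.stack([pairs[i].image for i in ids])
        masks = np.stack([pairs[i].mask for i in ids])
        yield imgs, masks


def _mean_iou(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> float:
    iou, _, _ = overlap_metrics(pred, truth, num_classes)
    return float(iou.mean())


def evaluate_loss_miou(
    model: SegmentationModel,
    pairs: list[SamplePair],
    config: TrainConfig,
    steps: int,
) -> tuple[float, float]:
    """Mean composite loss and mean per-image mIoU over ``steps`` cycled batches."""
    C = model.config.num_classes
    losses, mious = [], []
    n = len(pairs)
    for step in range(steps):
        pair = pairs[step % n]
        logits = model.forward(pair.image[None])
        probs = ad.softmax(logits, axis=-1)
        g = one_hot(pair.mask[None], C)
        losses.append(
            float(
                composite_loss(probs, g, config.dice_weight, config.cce_weight).item()
            )
        )
        pred = np.argmax(logits.data[0], axis=-1)
        mious.append(_mean_iou(pred, pair.mask, C))
    return float(np.mean(losses)), float(np.mean(mious))


def train(
    model: SegmentationModel,
    datasets: dict,
    config: TrainConfig,
    checkpoint_path=None,
    verbose: bool = False,
) -> TrainState:
    """Run the full training protocol; returns the final state with history.

    ``datasets`` must contain ``train`` and ``val`` lists of
    :class:`~spatioseg.synthio.SamplePair`.  Each epoch runs
    ``steps_per_epoch`` gradient steps at ``batch_size`` (cycling the
    training list when shorter), then evaluates ``validation_steps`` batches.
    The epoch-level callbacks update the learning rate, the early-stop flag
    and the in-memory best checkpoint; on stop (or at the end) the best
    weights are restored when ``restore_best`` is set.
    """
    train_pairs, val_pairs = datasets["train"], datasets["val"]
    if not train_pairs or not val_pairs:
        raise ValueError("train and val datasets must be non-empty")
    C = model.config.num_classes
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate, clipnorm=config.clipnorm)
    state = TrainState(current_lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best_weights = model.state_dict()
    n_train = len(train_pairs)
    cursor = 0
    order = rng.permutation(n_train)
    for epoch in range(1, config.epochs + 1):
        state.epoch = epoch
        opt.lr = state.current_lr
        epoch_losses, epoch_mious = [], []
        for _ in range(config.steps_per_epoch):
            ids = []
            for _ in range(config.batch_size):
                if cursor == n_train:
                    order = rng.permutation(n_train)
                    cursor = 0
                ids.append(order[cursor])
                cursor += 1
            imgs = np.stack([train_pairs[i].image for i in ids])
            masks = np.stack([train_pairs[i].mask for i in ids])
            opt.zero_grad()
            logits = model.forward(imgs)
            probs = ad.softmax(logits, axis=-1)
            g = one_hot(masks, C)
            loss = composite_loss(probs, g, config.dice_weight, config.cce_weight)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss {loss.item()} at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            pred = np.argmax(logits.data, axis=-1)
            epoch_mious.append(
                float(np.mean([_mean_iou(p, m, C) for p, m in zip(pred, masks)]))
            )
        val_loss, val_miou = evaluate_loss_miou(
            model, val_pairs, config, config.validation_steps
        )
        state.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "train_miou": float(np.mean(epoch_mious)),
                "val_miou": val_miou,
                "lr": state.current_lr,
            }
        )
        if verbose:
            h = state.history[-1]
            print(
                f"epoch {epoch:3d}  loss {h['train_loss']:.4f}  val_loss {val_loss:.4f}"
                f"  val_miou {val_miou:.4f}  lr {state.current_lr:.2e}"
            )
        # callbacks observe the epoch's val_loss; best tracking updates last
        plateau_step(state, val_loss, config.plateau_factor, config.plateau_patience, config.min_lr)
        early_stop_step(state, val_loss, config.early_stop_patience)
        if val_loss < state.best_val_loss:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            best_weights = model.state_dict()
            if checkpoint_path is not None:
                np.savez(checkpoint_path, **best_weights)
        if state.stopped:
            break
    if config.restore_best:
        model.load_state_dict(best_weights)
    return state


def predict(
    model: SegmentationModel, images: np.ndarray
) -> tuple[list[np.ndarray], list[float]]:
    """Per-image argmax masks plus wall-clock prediction time per image."""
    masks, times = [], []
    for img in images:
        t0 = time.perf_counter()
        mask = model.predict(img[None])[0]
        times.append(time.perf_counter() - t0)
        masks.append(mask)
    return masks, times
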