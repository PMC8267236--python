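"""Training: Adam optimization of the deep-supervision total loss, early
stopping on validation Dice, checkpointing and run logs.

Defaults follow the reference training recipe: Adam at learning rate 3e-4,
batch size 16, up to 100 epochs with an early-stop patience of 20 epochs
monitored on the mean validation Dice across the three regions.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .brats_io import SliceSample, labels_to_regions, RegionTargets
from .losses import LossWeights, total_loss
from .metrics import REGIONS, evaluate
from .network import AANet, NetConfig


@dataclasses.dataclass
class TrainConfig:
    """Everything that determines a training run (fully seeded)."""

    optimizer: str = "adam"
    learning_rate: float = 3e-4
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 20
    seed: int = 0
    loss: LossWeights = dataclasses.field(default_factory=LossWeights)
    net: NetConfig = dataclasses.field(default_factory=NetConfig)

    def __post_init__(self):
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (1 <= self.early_stop_patience <= self.max_epochs):
            raise ValueError("need 1 <= patience <= max_epochs")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("loss"), dict):
            d["loss"] = LossWeights(**d["loss"])
        if isinstance(d.get("net"), dict):
            net = dict(d["net"])
            for key in ("dilation_rates", "msc_positions"):
                if key in net and net[key] is not None:
                    net[key] = tuple(net[key])
            d["net"] = NetConfig(**net)
        return cls(**d)


def _batch_arrays(samples: Sequence[SliceSample]) -> Tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples]).astype(np.float32)
    targets = np.stack([labels_to_regions(s.label).stack() for s in samples])
    return images, targets


def train_step(model: AANet, optimizer: nn.Adam, images: np.ndarray,
               targets: np.ndarray, weights: LossWeights) -> Dict[str, float]:
    """One optimizer step on a batch; returns the loss breakdown."""
    optimizer.zero_grad()
    bundle = model(images)
    loss, breakdown = total_loss(bundle, targets, weights)
    loss.backward()
    optimizer.step()
    return breakdown


def predict_samples(model: AANet, samples: Sequence[SliceSample],
                    batch_size: int = 16,
                    enforce_nesting: bool = False) -> List[RegionTargets]:
    """Thresholded region predictions for a sample sequence (eval mode)."""
    preds = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        images = np.stack([s.image for s in chunk]).astype(np.float32)
        masks = model.predict_regions(images, enforce_nesting=enforce_nesting)
        preds.extend(RegionTargets.unchecked(m[0], m[1], m[2]) for m in masks)
    return preds


def mean_validation_dice(model: AANet, samples: Sequence[SliceSample],
                         batch_size: int = 16) -> Tuple[float, Dict[str, float]]:
    preds = predict_samples(model, samples, batch_size)
    truths = [labels_to_regions(s.label) for s in samples]
    report = evaluate(preds, truths)
    per_region = {r: float(report.table.loc[r, "dice"]) for r in REGIONS}
    return float(np.mean(list(per_region.values()))), per_region


@dataclasses.dataclass
class RunLog:
    rows: List[dict] = dataclasses.field(default_factory=list)

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit(train_samples: Sequence[SliceSample],
        val_samples: Sequence[SliceSample],
        config: TrainConfig,
        out_dir=None,
        verbose: bool = False) -> Tuple[AANet, RunLog]:
    """Train with early stopping; returns the best-validation model.

    Fully deterministic under (config, seed): the seed fixes weight
    initialization and the per-epoch shuffling order.
    """
    if not train_samples:
        raise ValueError("empty training set")
    if not val_samples:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(config.seed)
    model = AANet(config.net, rng=rng)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    log = RunLog()
    best_metric, best_state, best_epoch = -np.inf, None, -1
    epochs_since_best = 0
    for epoch in range(config.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_samples))
        model.train()
        sums, n_batches = {}, 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[start:start + config.batch_size]]
            images, targets = _batch_arrays(batch)
            breakdown = train_step(model, optimizer, images, targets, config.loss)
            n_batches += 1
            for k, v in breakdown.items():
                sums[k] = sums.get(k, 0.0) + v
        val_dice, per_region = mean_validation_dice(model, val_samples,
                                                    config.batch_size)
        row = {"epoch": epoch,
               **{k: v / n_batches for k, v in sums.items()},
               **{f"val_dice_{r}": per_region[r] for r in REGIONS},
               "val_dice_mean": val_dice,
               "learning_rate": config.learning_rate,
               "wall_time_s": time.perf_counter() - t0}
        log.append(**row)
        if verbose:
            print(f"epoch {epoch}: loss {row['L_total']:.4f} "
                  f"val dice {val_dice:.4f}")
        if val_dice > best_metric:
            best_metric, best_epoch = val_dice, epoch
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stop_patience:
                break
    model.load_state_dict(best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "checkpoint.npz", model, config)
        log.to_csv(out_dir / "runlog.csv")
    return model, log


def overfit(samples: Sequence[SliceSample], config: TrainConfig,
            max_steps: int = 200, target_dice: Optional[float] = None,
            check_every: int = 10) -> Tuple[AANet, List[float], float]:
    """Full-batch Adam steps on a fixed sample set (memorization check).

    Optionally stops as soon as the mean training Dice over the three
    regions exceeds ``target_dice``.  Returns the model, the per-step total
    losses, and the final mean training Dice.
    """
    rng = np.random.default_rng(config.seed)
    model = AANet(config.net, rng=rng)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    images, targets = _batch_arrays(samples)
    losses = []
    dice = 0.0
    for step in range(max_steps):
        model.train()
        breakdown = train_step(model, optimizer, images, targets, config.loss)
        losses.append(breakdown["L_total"])
        if target_dice is not None and (step + 1) % check_every == 0:
            dice, _ = mean_validation_dice(model, samples, len(samples))
            if dice >= target_dice:
                return model, losses, dice
    dice, _ = mean_validation_dice(model, samples, len(samples))
    return model, losses, dice


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: AANet, config: TrainConfig) -> None:
    state = model.state_dict()
    meta = json.dumps({"train_config": config.to_dict()})
    np.savez_compressed(path, __meta__=np.array(meta), **state)


def load_checkpoint(path) -> Tuple[AANet, TrainConfig]:
    with np.load(path, allow_pickle=False) as arc:
        meta = json.loads(str(arc["__meta__"]))
        state = {k: arc[k] for k in arc.files if k != "__meta__"}
    config = TrainConfig.from_dict(meta["train_config"])
    model = AANet(config.net)
    model.load_state_dict(state)
    model.eval()
    return model, config
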