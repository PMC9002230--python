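"""Training loop, Adam optimiser, cosine-annealed schedule and gate report.

The reference recipe follows the published training protocol of the model:
Adam (beta = 0.9/0.999, no weight decay), batch size 10, 400 epochs, initial
learning rate 1e-3 decayed to 1e-5 by cosine annealing after a 100-epoch
linear warmup from the minimum rate, input images fixed at 128 x 128, batch
normalisation with eps 1e-6 and momentum 0.1.  Desk-scale runs shrink epochs
and input size but keep the warmup fraction.

Training is deterministic for a fixed seed on one platform: the same seed
drives parameter initialisation, the train/validation split and the epoch
shuffles.  Per-epoch rows (epoch, lr, train loss, train Dice, val Dice) are
collected in a :class:`TrainResult` and the best-validation-Dice weights are
kept as the checkpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .losses import get_loss, softmax_foreground
from .metrics import confusion, rates, predict_mask
from .network import NetworkConfig, TGMLPUNet, save_checkpoint
from .synthetic import SegSample, load_dataset


@dataclass
class LossConfig:
    kind: str = "cross_entropy"
    alpha: float = 0.25
    gamma: float = 2.0

    def validate(self):
        if self.kind not in ("cross_entropy", "focal", "dice"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.kind == "focal":
            if not 0.0 < self.alpha < 1.0:
                raise ValueError("focal alpha must lie in (0, 1)")
            if self.gamma < 0:
                raise ValueError("focal gamma must be non-negative")


@dataclass
class TrainConfig:
    epochs: int = 400
    batch_size: int = 10
    lr_init: float = 1e-3
    lr_min: float = 1e-5
    warmup_epochs: int = 100
    bn_eps: float = 1e-6
    bn_momentum: float = 0.1
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    input_size: int = 128
    val_fraction: float = 0.2
    stop_at_train_dice: float | None = None

    def validate(self):
        if not 0 < self.lr_min <= self.lr_init:
            raise ValueError("require 0 < lr_min <= lr_init")
        if not 0 <= self.warmup_epochs < self.epochs:
            raise ValueError("require 0 <= warmup_epochs < epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")
        self.loss.validate()


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at ``epoch``: linear warmup then cosine annealing.

    Warmup ramps linearly from lr_min to lr_init over ``warmup_epochs``; the
    remaining epochs follow lr_min + (lr_init-lr_min)/2 * (1 + cos(pi t/T)).
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.warmup_epochs:
        frac = epoch / cfg.warmup_epochs
        return cfg.lr_min + (cfg.lr_init - cfg.lr_min) * frac
    t = epoch - cfg.warmup_epochs
    T = max(cfg.epochs - 1 - cfg.warmup_epochs, 1)
    cos = 0.5 * (1.0 + math.cos(math.pi * t / T))
    return cfg.lr_min + (cfg.lr_init - cfg.lr_min) * cos


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class EpochLog:
    epoch: int
    lr: float
    train_loss: float
    train_dice: float
    val_dice: float


@dataclass
class TrainResult:
    log: list[EpochLog]
    best_epoch: int
    best_val_dice: float
    checkpoint_path: Path | None
    gate_table: list[tuple[str, str, float, float, float]]

    @property
    def final_train_dice(self) -> float:
        return self.log[-1].train_dice if self.log else float("nan")

    def write_log(self, path):
        with open(path, "w") as fh:
            fh.write("epoch\tlr\ttrain_loss\ttrain_dice\tval_dice\n")
            for row in self.log:
                fh.write(f"{row.epoch}\t{row.lr:.8f}\t{row.train_loss:.6f}\t"
                         f"{row.train_dice:.6f}\t{row.val_dice:.6f}\n")


def _stack(samples: list[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples])[:, None, :, :]
    masks = np.stack([s.mask for s in samples]).astype(np.float64)
    return images.astype(ad.DEFAULT_DTYPE), masks


def _batch_dice(prob: np.ndarray, masks: np.ndarray) -> tuple[int, int]:
    """Summed (2TP, 2TP+FP+FN) contributions over a batch."""
    num = den = 0
    for k in range(prob.shape[0]):
        c = confusion(predict_mask(prob[k]), masks[k].astype(np.uint8))
        num += 2 * c.tp
        den += 2 * c.tp + c.fp + c.fn
    return num, den


def train(model_config: NetworkConfig, train_config: TrainConfig,
          data, out_dir=None) -> TrainResult:
    """Optimise the model on a dataset directory or an in-memory sample list."""
    train_config.validate()
    model_config.validate()
    if isinstance(data, (str, Path)):
        samples = load_dataset(data, train_config.input_size)
    else:
        samples = list(data)
    if not samples:
        raise ValueError("empty dataset")

    rng = np.random.default_rng(train_config.seed)
    order = rng.permutation(len(samples))
    n_val = int(round(train_config.val_fraction * len(samples)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training samples after split")
    train_images, train_masks = _stack([samples[i] for i in train_idx])
    if len(val_idx):
        val_images, val_masks = _stack([samples[i] for i in val_idx])
    else:  # fall back to scoring on the training set
        val_images, val_masks = train_images, train_masks

    model = TGMLPUNet(model_config, seed=train_config.seed)
    loss_fn = get_loss(train_config.loss.kind, train_config.loss.alpha,
                       train_config.loss.gamma)
    optimiser = Adam(model.parameters())

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    best_val, best_epoch, best_state = -1.0, -1, None
    log: list[EpochLog] = []
    n_train = len(train_idx)
    for epoch in range(train_config.epochs):
        optimiser.lr = lr_at(epoch, train_config)
        model.train()
        perm = rng.permutation(n_train)
        losses = []
        dice_num = dice_den = 0
        for start in range(0, n_train, train_config.batch_size):
            idx = perm[start:start + train_config.batch_size]
            xb = ad.Tensor(train_images[idx])
            mb = train_masks[idx]
            model.zero_grad()
            prob = softmax_foreground(model(xb))
            loss = loss_fn(prob, mb)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            optimiser.step()
            losses.append(value)
            num, den = _batch_dice(prob.data, mb)
            dice_num += num
            dice_den += den
        train_dice = dice_num / dice_den if dice_den else 1.0
        val_dice = evaluate_dice(model, val_images, val_masks,
                                 train_config.batch_size)
        log.append(EpochLog(epoch, optimiser.lr, float(np.mean(losses)),
                            train_dice, val_dice))
        if val_dice > best_val:
            best_val, best_epoch = val_dice, epoch
            best_state = model.state_dict()
        if (train_config.stop_at_train_dice is not None
                and train_dice >= train_config.stop_at_train_dice):
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    checkpoint_path = None
    if out_dir is not None:
        checkpoint_path = out_dir / "checkpoint.npz"
        save_checkpoint(model, checkpoint_path)
        result_gates = gate_table(model)
        TrainResult(log, best_epoch, best_val, checkpoint_path,
                    result_gates).write_log(out_dir / "log.tsv")
        _write_metadata(out_dir, model_config, train_config)
    return TrainResult(log, best_epoch, best_val, checkpoint_path,
                       gate_table(model))


def _write_metadata(out_dir: Path, model_config, train_config):
    import json

    meta = {"model": model_config.to_dict(),
            "train": asdict(train_config),
            "seed": train_config.seed}
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2))


def evaluate_dice(model: TGMLPUNet, images: np.ndarray, masks: np.ndarray,
                  batch_size: int = 10) -> float:
    """Aggregate Dice of thresholded predictions (evaluation mode)."""
    model.eval()
    num = den = 0
    for start in range(0, images.shape[0], batch_size):
        xb = ad.Tensor(images[start:start + batch_size])
        prob = softmax_foreground(model(xb)).data
        n, d = _batch_dice(prob, masks[start:start + batch_size])
        num += n
        den += d
    model.train()
    return num / den if den else 1.0


def gate_table(model: TGMLPUNet) -> list[tuple[str, str, float, float, float]]:
    """(branch, stage, g_c, g_h, g_w) rows for every learnable gate."""
    return [(branch, stage, float(g[0]), float(g[1]), float(g[2]))
            for branch, stage, g in model.gates()]
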