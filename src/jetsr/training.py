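"""Region-split MSE loss, learning-rate schedule and the training loop.

The loss is the sum of two mean-squared-error terms computed separately over
fluid and non-fluid voxels (summed over the three velocity components), so
the sparse fluid region is not swamped by the background.  Training follows
Adam with an initial learning rate divided by sqrt(2) every 14 epochs, and
model checkpoints are kept by minimum validation relative speed error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import relative_speed_error
from .models import MAGNITUDE_SCALE, SRNet, save_checkpoint
from .nn import Adam
from .patches import PatchPair

__all__ = [
    "TrainConfig", "LossBreakdown", "PatchDataset",
    "mse_loss", "lr_schedule", "train",
]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-4
    decay_factor: float = float(np.sqrt(2.0))
    decay_interval: int = 14        # epochs between learning-rate divisions
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.initial_lr, self.decay_factor, self.decay_interval,
               self.batch_size, self.epochs) <= 0:
            raise ValueError("all training parameters must be positive")


@dataclass(frozen=True)
class LossBreakdown:
    fluid_mse: float
    nonfluid_mse: float

    @property
    def total(self) -> float:
        return self.fluid_mse + self.nonfluid_mse


def mse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> LossBreakdown:
    """Region-split velocity MSE.

    ``pred``/``target`` are velocity patches with components on the last
    axis; ``mask`` is the fluid partition of the spatial axes.  Each term is
    the mean over that region's voxels of the squared error summed across
    components; an empty region contributes 0.
    """
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape or mask.shape != pred.shape[:-1]:
        raise ValueError("pred, target and mask shapes are inconsistent")
    sq = ((pred - target) ** 2).sum(axis=-1)
    fluid = np.asarray(mask, dtype=bool)
    f = float(sq[fluid].mean()) if fluid.any() else 0.0
    n = float(sq[~fluid].mean()) if (~fluid).any() else 0.0
    return LossBreakdown(fluid_mse=f, nonfluid_mse=n)


def _loss_and_grad(pred, target, mask):
    """Channels-first batch loss with gradient w.r.t. ``pred``.

    ``pred``/``target``: (B, 3, n, n, n); ``mask``: (B, n, n, n).
    """
    diff = pred - target
    sq = (diff ** 2).sum(axis=1)
    fluid = mask
    n_f = int(fluid.sum())
    n_n = fluid.size - n_f
    f = float(sq[fluid].sum() / n_f) if n_f else 0.0
    n = float(sq[~fluid].sum() / n_n) if n_n else 0.0
    w = np.where(fluid, 1.0 / max(n_f, 1) * (n_f > 0),
                 1.0 / max(n_n, 1) * (n_n > 0)).astype(pred.dtype)
    grad = 2.0 * diff * w[:, None]
    return LossBreakdown(fluid_mse=f, nonfluid_mse=n), grad


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant decay: ``lr0 / decay^floor(epoch / interval)``."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.initial_lr / cfg.decay_factor ** (epoch // cfg.decay_interval)


@dataclass
class PatchDataset:
    """Normalised training tensors built from patch pairs.

    ``x``: (N, 6, 12, 12, 12) -- velocity / VENC then magnitude / 240;
    ``y``: (N, 3, 48, 48, 48) -- HR velocity / VENC;
    ``mask``: (N, 48, 48, 48); ``venc``: (N, 3) m/s.
    """

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    venc: np.ndarray

    def __len__(self) -> int:
        return self.x.shape[0]

    @classmethod
    def from_pairs(cls, pairs: list[PatchPair]) -> "PatchDataset":
        if not pairs:
            raise ValueError("empty patch list")
        xs, ys, ms, vs = [], [], [], []
        for p in pairs:
            venc = np.asarray(p.venc, dtype=np.float32)
            v = np.moveaxis(p.lr[..., :3], -1, 0) / venc[:, None, None, None]
            m = np.moveaxis(p.lr[..., 3:], -1, 0) / MAGNITUDE_SCALE
            xs.append(np.concatenate([v, m], axis=0).astype(np.float32))
            hr = np.moveaxis(p.hr, -1, 0) / venc[:, None, None, None]
            ys.append(hr.astype(np.float32))
            ms.append(p.hr_mask.astype(bool))
            vs.append(venc)
        return cls(
            x=np.stack(xs), y=np.stack(ys), mask=np.stack(ms), venc=np.stack(vs)
        )


def validation_re(model, data: PatchDataset, batch: int = 8) -> float:
    """Mean per-patch relative speed error on physical velocities."""
    res = []
    for s in range(0, len(data), batch):
        x = data.x[s:s + batch]
        pred = model.forward(x, train=False)
        venc = data.venc[s:s + batch]
        pred_phys = pred * venc[:, :, None, None, None]
        targ_phys = data.y[s:s + batch] * venc[:, :, None, None, None]
        for b in range(x.shape[0]):
            m = data.mask[s + b]
            if not m.any():
                continue
            res.append(relative_speed_error(
                np.moveaxis(pred_phys[b], 0, -1),
                np.moveaxis(targ_phys[b], 0, -1), m,
            ))
    if not res:
        raise ValueError("no validation patch contains fluid voxels")
    return float(np.mean(res))


def train(
    model: SRNet,
    train_data: PatchDataset,
    val_data: PatchDataset,
    cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train ``model``; returns the per-epoch history.

    History rows carry (epoch, lr, train_loss, val_re); row ``epoch = 0``
    records the untrained validation error.  The best checkpoint (minimum
    validation relative speed error) is restored into ``model`` at the end
    and, with ``checkpoint_dir``, both best and last weights are saved.
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.initial_lr)

    def snapshot():
        return [p.value.copy() for p in model.params()]

    rows = [{
        "epoch": 0, "lr": lr_schedule(0, cfg), "train_loss": np.nan,
        "val_re": validation_re(model, val_data),
    }]
    best = {"val_re": rows[0]["val_re"], "epoch": 0, "params": snapshot()}

    n = len(train_data)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_schedule(epoch - 1, cfg)
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            pred = model.forward(train_data.x[idx], train=True)
            loss, grad = _loss_and_grad(
                pred, train_data.y[idx], train_data.mask[idx]
            )
            if not np.isfinite(loss.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss.total)
        val_re = validation_re(model, val_data)
        rows.append({
            "epoch": epoch, "lr": opt.lr,
            "train_loss": float(np.mean(losses)), "val_re": val_re,
        })
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  "
                  f"loss {rows[-1]['train_loss']:.5f}  val_re {val_re:.4f}")
        if val_re < best["val_re"]:
            best = {"val_re": val_re, "epoch": epoch, "params": snapshot()}
        if checkpoint_dir is not None:
            save_checkpoint(
                model, Path(checkpoint_dir) / "last.npz",
                extra={"epoch": epoch, "val_re": val_re},
            )

    for p, v in zip(model.params(), best["params"]):
        p.value[...] = v
    if checkpoint_dir is not None:
        save_checkpoint(
            model, Path(checkpoint_dir) / "best.npz",
            extra={"epoch": best["epoch"], "val_re": best["val_re"]},
        )
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best["epoch"]
    history.attrs["best_val_re"] = best["val_re"]
    return history
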