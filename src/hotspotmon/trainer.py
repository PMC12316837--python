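"""Training and evaluation of the hotspot detector.

Optimization follows the study conditions: mean binary cross-entropy over
output pixels, stochastic gradient descent with momentum 0.8, and a smooth
exponential learning-rate decay

    eta(t) = eta0 * r^(t / v),   v = floor(N_epoch * N_train / S_batch),

i.e. one full decade of decay (r = 0.1 from eta0 = 0.01) over the whole
training run.  Batch size 32 and 40 epochs at full scale.  Everything is
seeded: data order, weight initialization and noise draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .hotspot_net import Network, bce_loss
from .metrics import MetricsReport, evaluate_images, threshold_sweep

__all__ = ["TrainConfig", "TrainHistory", "lr_at_step", "train", "evaluate", "sweep_snr", "sweep_alpha"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 32
    eta0: float = 0.01
    decay_rate: float = 0.1
    momentum: float = 0.8
    seed: int = 0
    checkpoint_policy: str = "best_val"  # or "final"

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 0 or self.eta0 <= 0 or self.decay_rate <= 0:
            raise ValueError("invalid training hyperparameters")
        if self.checkpoint_policy not in ("best_val", "final"):
            raise ValueError("checkpoint_policy must be 'best_val' or 'final'")

    def decay_steps(self, n_train: int) -> int:
        """v = floor(N_epoch * N_train / S_batch), the full run's step count."""
        return max(1, math.floor(self.epochs * n_train / self.batch_size))


def lr_at_step(config: TrainConfig, t: int, v: int) -> float:
    """Continuous exponential decay eta0 * r^(t/v) at optimizer step t."""
    if t < 0:
        raise ValueError("step must be >= 0")
    return config.eta0 * config.decay_rate ** (t / v)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "best_epoch": self.best_epoch,
        }


class _SGDMomentum:
    def __init__(self, model: Network, momentum: float):
        self.momentum = momentum
        self.velocity = {
            name: np.zeros_like(layer.params[pname])
            for name, layer, pname in model.parameters()
        }

    def step(self, model: Network, lr: float) -> None:
        for name, layer, pname in model.parameters():
            g = layer.grads[pname]
            v = self.momentum * self.velocity[name] - lr * g
            self.velocity[name] = v
            layer.params[pname] += v


def _eval_loss_acc(model: Network, x: np.ndarray, y: np.ndarray, batch: int = 256):
    losses, correct, total = [], 0, 0
    for start in range(0, len(x), batch):
        xb, yb = x[start : start + batch], y[start : start + batch]
        probs = model.forward(xb, train=False)
        losses.append(bce_loss(probs, yb) * len(xb))
        correct += int(np.sum((probs > 0.5) == (yb > 0.5)))
        total += yb.size
    return sum(losses) / len(x), correct / total


def train(
    model: Network, dataset: Dataset, config: TrainConfig | None = None, verbose: bool = False
) -> TrainHistory:
    """Train ``model`` on the dataset's train split; returns the history.

    With ``checkpoint_policy='best_val'`` the weights of the best-validation
    epoch are restored into the model at the end.  A non-finite loss aborts
    with a diagnostic.  Zero epochs return the untouched model and an empty
    history.
    """
    cfg = config or TrainConfig()
    history = TrainHistory()
    if cfg.epochs == 0:
        return history

    rng = np.random.default_rng(cfg.seed)
    train_idx = dataset.splits["train"]
    val_idx = dataset.splits["val"]
    x_train = dataset.network_inputs(train_idx)
    y_train = dataset.labels[train_idx].astype(np.float32)
    x_val = dataset.network_inputs(val_idx)
    y_val = dataset.labels[val_idx].astype(np.float32)

    v = cfg.decay_steps(len(train_idx))
    opt = _SGDMomentum(model, cfg.momentum)
    best_val, best_params = np.inf, None
    t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss, correct, total = 0.0, 0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            probs = model.forward(xb, train=True)
            loss = bce_loss(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {t}"
                )
            model.backward_from_bce(probs, yb)
            opt.step(model, lr_at_step(cfg, t, v))
            t += 1
            epoch_loss += loss * len(sel)
            correct += int(np.sum((probs > 0.5) == (yb > 0.5)))
            total += yb.size

        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val) if len(val_idx) else (np.nan, np.nan)
        history.train_loss.append(epoch_loss / len(order))
        history.train_accuracy.append(correct / total)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if len(val_idx) and val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            if cfg.checkpoint_policy == "best_val":
                best_params = [
                    (layer, pname, layer.params[pname].copy())
                    for _, layer, pname in model.parameters()
                ]
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}: train loss {history.train_loss[-1]:.4f} "
                f"acc {history.train_accuracy[-1]:.4f} | val loss {val_loss:.4f} acc {val_acc:.4f}"
            )

    if cfg.checkpoint_policy == "best_val" and best_params is not None:
        for layer, pname, value in best_params:
            layer.params[pname] = value
    return history


def evaluate(
    model: Network,
    dataset: Dataset,
    split: str = "test",
    snr_test_db: float | None = None,
    alpha_dec: float = 0.5,
    rng: np.random.Generator | None = None,
) -> MetricsReport:
    """Score the model on a split, optionally re-noised at ``snr_test_db``.

    ``snr_test_db=None`` evaluates the stored tensors (noised at the
    training SNR); any other value re-noises the stored clean fields.
    """
    idx = dataset.splits[split]
    if snr_test_db is None:
        x = dataset.network_inputs(idx)
    else:
        rng = rng or np.random.default_rng(0)
        x = dataset.renoised_inputs(idx, snr_test_db, rng)
    probs = _forward_batched(model, x)
    preds = probs > alpha_dec
    return evaluate_images(preds, dataset.labels[idx] > 0, dataset.tumor_mask)


def _forward_batched(model: Network, x: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [model.forward(x[s : s + batch], train=False) for s in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def sweep_snr(
    model: Network,
    dataset: Dataset,
    snr_grid,
    split: str = "test",
    alpha_dec: float = 0.5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Mean accuracy (and Dice/danger) across a test-SNR grid."""
    rows = {"snr_db": [], "mean_accuracy": [], "mean_dice": [], "danger_accuracy": []}
    for snr in snr_grid:
        rng = np.random.default_rng(seed)
        report = evaluate(model, dataset, split, float(snr), alpha_dec, rng)
        rows["snr_db"].append(float(snr))
        rows["mean_accuracy"].append(report.mean_accuracy)
        rows["mean_dice"].append(np.nan if report.mean_dice is None else report.mean_dice)
        rows["danger_accuracy"].append(
            np.nan if report.danger_accuracy is None else report.danger_accuracy
        )
    return {k: np.asarray(v) for k, v in rows.items()}


def sweep_alpha(
    model: Network,
    dataset: Dataset,
    alphas,
    split: str = "test",
    snr_test_db: float | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Decision-threshold sweep on one split (probability maps reused)."""
    idx = dataset.splits[split]
    if snr_test_db is None:
        x = dataset.network_inputs(idx)
    else:
        x = dataset.renoised_inputs(idx, snr_test_db, np.random.default_rng(seed))
    probs = _forward_batched(model, x)
    return threshold_sweep(probs, dataset.labels[idx] > 0, dataset.tumor_mask, alphas)
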