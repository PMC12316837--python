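"""Pixel-wise and scenario-level evaluation of hotspot images.

Pixel level: accuracy s_acc = (TP+TN)/(TP+TN+FP+FN) and Dice overlap
s_Dice = 2TP/(2TP+FP+FN) between predicted and true binary hotspot images.
Scenario level: a scenario is *dangerous* when at least one hotspot lies
outside the tumor disc (heating the tumor is the goal, heating healthy
tissue is not), and the danger accuracy is the recall
TP_danger/(TP_danger+FN_danger) over the truly dangerous scenarios.

Dice is undefined when both images are empty; such pairs carry a ``None``
score and are excluded from averages (reported alongside the mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy_score",
    "dice_score",
    "danger_status",
    "danger_accuracy",
    "MetricsReport",
    "evaluate_images",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def accuracy_score(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise ValueError("no pixels compared")
    return (counts.tp + counts.tn) / counts.total


def dice_score(counts: ConfusionCounts) -> float | None:
    """Dice overlap; ``None`` when truth and prediction are both empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return None
    return 2 * counts.tp / denom


def danger_status(hotspots: np.ndarray, tumor_mask: np.ndarray) -> bool:
    """True iff any hotspot pixel lies outside the tumor region."""
    hotspots = np.asarray(hotspots, dtype=bool)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if hotspots.shape != tumor_mask.shape:
        raise ValueError("hotspot image and tumor mask shapes differ")
    return bool(np.any(hotspots & ~tumor_mask))


def danger_accuracy(truth_statuses, predicted_statuses) -> float:
    """Recall of danger detection over truly dangerous scenarios."""
    truth = np.asarray(truth_statuses, dtype=bool)
    pred = np.asarray(predicted_statuses, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError("status vectors differ in length")
    positives = int(truth.sum())
    if positives == 0:
        raise ValueError("no danger-positive scenarios: danger accuracy undefined")
    tp_danger = int(np.sum(truth & pred))
    return tp_danger / positives


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate scores over a set of scenarios."""

    n_scenarios: int
    pixel_accuracy: float  # pooled over all pixels of all scenarios
    mean_accuracy: float  # mean of per-scenario s_acc
    mean_dice: float | None  # mean of defined per-scenario Dice scores
    n_dice_defined: int
    danger_accuracy: float | None  # None when no danger-positive scenarios
    n_danger_positive: int
    per_sample_accuracy: np.ndarray
    per_sample_dice: np.ndarray  # NaN where undefined

    def summary(self) -> str:
        dice = "n/a" if self.mean_dice is None else f"{self.mean_dice:.3f}"
        danger = "n/a" if self.danger_accuracy is None else f"{self.danger_accuracy:.3f}"
        return (
            f"{self.n_scenarios} scenarios | pixel acc {self.pixel_accuracy:.3f} | "
            f"mean s_acc {self.mean_accuracy:.3f} | mean s_Dice {dice} "
            f"({self.n_dice_defined} defined) | danger acc {danger} "
            f"({self.n_danger_positive} positive)"
        )


def evaluate_images(
    predictions: np.ndarray, truths: np.ndarray, tumor_mask: np.ndarray
) -> MetricsReport:
    """Score a stack of predicted vs true hotspot images.

    ``predictions`` and ``truths`` are (n_scenarios, n, n) binary stacks;
    ``tumor_mask`` the (n, n) tumor disc of the phantom.
    """
    predictions = np.asarray(predictions, dtype=bool)
    truths = np.asarray(truths, dtype=bool)
    if predictions.shape != truths.shape:
        raise ValueError("prediction and truth stacks differ in shape")

    accs, dices = [], []
    truth_statuses, pred_statuses = [], []
    pooled_correct = 0
    for pred, truth in zip(predictions, truths):
        counts = confusion_counts(pred, truth)
        accs.append(accuracy_score(counts))
        d = dice_score(counts)
        dices.append(np.nan if d is None else d)
        pooled_correct += counts.tp + counts.tn
        truth_statuses.append(danger_status(truth, tumor_mask))
        pred_statuses.append(danger_status(pred, tumor_mask))

    accs = np.array(accs)
    dices = np.array(dices)
    defined = ~np.isnan(dices)
    n_pos = int(np.sum(truth_statuses))
    return MetricsReport(
        n_scenarios=len(accs),
        pixel_accuracy=pooled_correct / truths.size,
        mean_accuracy=float(accs.mean()),
        mean_dice=float(dices[defined].mean()) if defined.any() else None,
        n_dice_defined=int(defined.sum()),
        danger_accuracy=danger_accuracy(truth_statuses, pred_statuses) if n_pos else None,
        n_danger_positive=n_pos,
        per_sample_accuracy=accs,
        per_sample_dice=dices,
    )


def threshold_sweep(
    probability_maps: np.ndarray,
    truths: np.ndarray,
    tumor_mask: np.ndarray,
    alphas,
) -> dict[str, np.ndarray]:
    """Mean s_acc and danger accuracy across a decision-threshold grid.

    Returns a table-like dict with keys ``alpha``, ``mean_accuracy``,
    ``danger_accuracy`` (NaN where undefined).
    """
    alphas = np.asarray(alphas, dtype=float)
    mean_acc = np.empty_like(alphas)
    danger_acc = np.empty_like(alphas)
    for i, alpha in enumerate(alphas):
        report = evaluate_images(probability_maps > alpha, truths, tumor_mask)
        mean_acc[i] = report.mean_accuracy
        danger_acc[i] = np.nan if report.danger_accuracy is None else report.danger_accuracy
    return {"alpha": alphas, "mean_accuracy": mean_acc, "danger_accuracy": danger_acc}
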