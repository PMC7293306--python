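"""Hold-out validation of the severity classifiers.

Covers the class-label metrics (confusion counts, accuracy, precision,
recall, F1), the probability metrics (Brier score, ROC AUC) and the
reliability curve used to judge calibration.  Precision and recall are
reported as absent (None) when their denominator is zero rather than
coerced to 0, so F1 is never silently deflated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple, Sequence, TypeVar

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "ClassificationResult",
    "ValidationReport",
    "holdout_split",
    "classification_metrics",
    "brier_score",
    "roc_auc",
    "reliability_curve",
    "reliability_slope",
    "plot_reliability_curve",
    "evaluate_probabilities",
]

T = TypeVar("T")


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int


class ClassificationResult(NamedTuple):
    confusion: ConfusionCounts
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None


def holdout_split(
    records: Sequence[T], test_fraction: float, seed: int = 0
) -> tuple[list[T], list[T]]:
    """Disjoint, exhaustive (train, test) partition by seeded uniform shuffle.

    Test size is round(n * test_fraction) (banker's rounding); no
    stratification is applied.
    """
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n_test >= n:
        raise ValidationError(
            f"degenerate split: {n} records at fraction {test_fraction} "
            f"gives test size {n_test}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    test = [records[i] for i in perm[:n_test]]
    train = [records[i] for i in perm[n_test:]]
    return train, test


def _check_paired(labels: Sequence[int], probabilities: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValidationError(
            f"labels and probabilities must be equal-length 1-D, got {y.shape} vs {p.shape}"
        )
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary (0/1)")
    return y.astype(int), p


def classification_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> ClassificationResult:
    """Confusion table and derived metrics; prediction is 1 iff probability >= threshold."""
    y, p = _check_paired(labels, probabilities)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    accuracy = (tp + tn) / len(y)
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return ClassificationResult(ConfusionCounts(tp, fp, fn, tn), accuracy, precision, recall, f1)


def brier_score(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Mean squared difference between predicted probability and the 0/1 class."""
    y, p = _check_paired(labels, probabilities)
    return float(np.mean((p - y) ** 2))


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    y, p = _check_paired(labels, probabilities)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, p))


def reliability_curve(
    labels: Sequence[int], probabilities: Sequence[float], n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """(mean predicted, observed positive fraction, count) per non-empty bin.

    Bins are equal-width on [0, 1], right-open except the last.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    y, p = _check_paired(labels, probabilities)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1] for binning")
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    curve = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        if count == 0:
            continue
        curve.append((float(p[mask].mean()), float(y[mask].mean()), count))
    return curve


def reliability_slope(curve: Sequence[tuple[float, float, int]]) -> float:
    """Slope of the unweighted least-squares line through the curve points.

    1.0 indicates perfect calibration; <1 overconfident, >1 underconfident.
    """
    if len(curve) < 2:
        raise ValidationError("need at least 2 bins to fit a reliability slope")
    x = np.array([b[0] for b in curve])
    y = np.array([b[1] for b in curve])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


@dataclass(frozen=True)
class ValidationReport:
    """All hold-out metrics for one outcome model, JSON-serializable."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    brier: float
    roc_auc: float
    reliability_bins: tuple[tuple[float, float, int], ...]
    confusion: tuple[int, int, int, int]  # tp, fp, fn, tn

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @staticmethod
    def from_json(text: str) -> "ValidationReport":
        data = json.loads(text)
        data["reliability_bins"] = tuple(tuple(b) for b in data["reliability_bins"])
        data["confusion"] = tuple(data["confusion"])
        return ValidationReport(**data)


def evaluate_probabilities(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float = 0.5,
    n_bins: int = 10,
) -> ValidationReport:
    """Bundle every hold-out metric for one set of predicted probabilities."""
    result = classification_metrics(labels, probabilities, threshold)
    return ValidationReport(
        accuracy=result.accuracy,
        precision=result.precision,
        recall=result.recall,
        f1=result.f1,
        brier=brier_score(labels, probabilities),
        roc_auc=roc_auc(labels, probabilities),
        reliability_bins=tuple(reliability_curve(labels, probabilities, n_bins)),
        confusion=tuple(result.confusion),
    )


def plot_reliability_curve(
    curve: Sequence[tuple[float, float, int]], path: str | Path, title: str = "Reliability curve"
) -> None:
    """Render predicted probability vs observed positive fraction with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = [b[0] for b in curve]
    y = [b[1] for b in curve]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfectly calibrated")
    ax.plot(x, y, "o-", label="model")
    ax.set_xlabel("Mean predicted probability")
    ax.set_ylabel("Fraction of positives")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
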