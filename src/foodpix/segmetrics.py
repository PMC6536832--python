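"""Semantic-segmentation evaluation: confusion matrix and the four measures.

Given ground-truth and predicted label masks over ``n_cl`` classes, the
confusion matrix ``n`` has entry ``n[i, j]`` = number of pixels of true
class ``i`` predicted as class ``j``, and ``t_i = sum_j n[i, j]`` is the
total true pixel count of class ``i``. The four standard measures are

* pixel accuracy        ``sum_i n_ii / sum_i t_i``
* mean accuracy         ``(1 / n_cl') sum_i n_ii / t_i``
* mean IU               ``(1 / n_cl') sum_i n_ii / (t_i + sum_j n_ji - n_ii)``
* frequency-weighted IU ``(sum_k t_k)^-1 sum_i t_i n_ii / (t_i + sum_j n_ji - n_ii)``

Empty-class convention: classes absent from both truth and prediction are
excluded from the unweighted means; classes predicted but absent from truth
contribute IU 0 to mean IU. This never divides by zero. Evaluation over a
set of images pools one global confusion matrix (the elementwise sum of the
per-image matrices), not a mean of per-image scores; the background is an
ordinary class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from foodpix.imageset import ClassRegistry, DatasetManifest, ManifestItem, read_mask


@dataclass(frozen=True)
class ConfusionMatrix:
    """n_cl x n_cl pixel counts; entry (i, j) = true class i predicted as j."""

    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if n.ndim != 2 or n.shape[0] != n.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {n.shape}")
        if n.size == 0:
            raise ValueError("confusion matrix must be non-empty")
        if (n < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "n", n.astype(np.int64))

    @property
    def n_cl(self) -> int:
        return self.n.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Per-class true pixel totals ``t_i`` (row sums)."""
        return self.n.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.n_cl != other.n_cl:
            raise ValueError("cannot pool matrices of different class counts")
        return ConfusionMatrix(self.n + other.n)


@dataclass(frozen=True)
class SegReport:
    pixel_accuracy: float
    mean_accuracy: float
    mean_iu: float
    freq_weighted_iu: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pixel_accuracy": self.pixel_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "mean_iu": self.mean_iu,
            "freq_weighted_iu": self.freq_weighted_iu,
        }


def confusion(truth: np.ndarray, pred: np.ndarray, n_cl: int) -> ConfusionMatrix:
    """Build the confusion matrix from a truth/prediction mask pair."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(
            f"truth shape {truth.shape} != prediction shape {pred.shape}"
        )
    if truth.size and (int(truth.max()) >= n_cl or int(pred.max()) >= n_cl):
        raise ValueError(
            f"label >= n_cl={n_cl} (max truth {int(truth.max())}, "
            f"max pred {int(pred.max())})"
        )
    flat = truth.astype(np.int64).ravel() * n_cl + pred.astype(np.int64).ravel()
    counts = np.bincount(flat, minlength=n_cl * n_cl)
    return ConfusionMatrix(counts.reshape(n_cl, n_cl))


def pixel_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of pixels assigned their true class: trace over total."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix: no evaluated pixels")
    return float(np.trace(cm.n) / total)


def mean_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean per-class recall over classes present in ground truth."""
    t = cm.t
    present = t > 0
    if not present.any():
        raise ValueError("no class present in ground truth")
    diag = np.diag(cm.n)
    return float(np.mean(diag[present] / t[present]))


def _per_class_iu(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-class IU and a mask of classes present in truth or prediction."""
    t = cm.t
    col = cm.n.sum(axis=0)
    diag = np.diag(cm.n)
    union = t + col - diag
    present = union > 0
    iu = np.zeros(cm.n_cl, dtype=float)
    iu[present] = diag[present] / union[present]
    return iu, present


def mean_iu(cm: ConfusionMatrix) -> float:
    """Unweighted mean per-class IU over classes present in truth or prediction."""
    iu, present = _per_class_iu(cm)
    if not present.any():
        raise ValueError("no class present in truth or prediction")
    return float(np.mean(iu[present]))


def freq_weighted_iu(cm: ConfusionMatrix) -> float:
    """Per-class IU weighted by each class's true pixel count."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix: no evaluated pixels")
    iu, _ = _per_class_iu(cm)
    return float(np.dot(cm.t, iu) / total)


def report(cm: ConfusionMatrix) -> SegReport:
    """All four measures from one pooled confusion matrix."""
    return SegReport(
        pixel_accuracy=pixel_accuracy(cm),
        mean_accuracy=mean_accuracy(cm),
        mean_iu=mean_iu(cm),
        freq_weighted_iu=freq_weighted_iu(cm),
    )


def evaluate(
    items: Sequence[ManifestItem] | DatasetManifest,
    predictions: str | Path | Mapping[str, np.ndarray],
    registry: ClassRegistry,
) -> SegReport:
    """Evaluate predictions against ground truth over a manifest subset.

    ``predictions`` is either a directory containing one prediction mask PNG
    per image (named ``<image stem>_pred.png``) or a mapping from image path
    to prediction array. A single confusion matrix is pooled over all pairs
    and the four measures computed from it; the background counts as a class.
    """
    if isinstance(items, DatasetManifest):
        items = items.items
    if len(items) == 0:
        raise ValueError("cannot evaluate an empty set of images")
    n_cl = registry.n_classes
    pooled = ConfusionMatrix(np.zeros((n_cl, n_cl), dtype=np.int64))
    for it in items:
        truth = read_mask(it.mask, registry)
        if isinstance(predictions, Mapping):
            if it.image not in predictions:
                raise FileNotFoundError(f"no prediction supplied for {it.image}")
            pred = np.asarray(predictions[it.image])
        else:
            pred_path = Path(predictions) / f"{Path(it.image).stem}_pred.png"
            if not pred_path.exists():
                raise FileNotFoundError(
                    f"missing prediction mask for {it.image}: {pred_path}"
                )
            pred = read_mask(pred_path, registry)
        pooled = pooled + confusion(truth, pred, n_cl)
    return report(pooled)
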