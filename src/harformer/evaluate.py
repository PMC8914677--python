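"""Evaluation and interpretability artifacts.

Timestep-level confusion matrix and class-wise precision/recall/F1/support,
attention heatmaps, cosine similarity of learned position-embedding rows,
the within-half vs cross-half attention block-mass statistic used to probe
whether a trained model splits a window at the augmentation change point,
and a change-point estimator for predicted label tracks.

Numeric matrices are the tested surface; PNG rendering is a thin optional
layer (higher attention weight maps to a paler colour).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .model import AttentionRecord

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "classwise_metrics",
    "evaluation_report",
    "attention_heatmap",
    "render_heatmap_png",
    "position_embedding_similarity",
    "attention_block_mass",
    "estimate_change_point",
]


def confusion_matrix(
    predictions: np.ndarray, labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """K x K counts; entry (i, j) = timesteps with true i predicted j."""
    predictions = np.asarray(predictions).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    for arr, what in ((predictions, "prediction"), (labels, "label")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{what} outside 0..{n_classes - 1}")
    return _sk_confusion(labels, predictions, labels=np.arange(n_classes))


def classwise_metrics(confusion: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class precision, recall, F1 and support from a confusion matrix.

    Zero denominators (a class never predicted, or absent from the truth)
    yield 0 with a warning.
    """
    confusion = np.asarray(confusion)
    if np.any(confusion < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    k = confusion.shape[0]
    diag = np.diag(confusion).astype(float)
    col = confusion.sum(axis=0).astype(float)
    row = confusion.sum(axis=1).astype(float)
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn(
            "zero denominator in precision/recall; reporting 0 for the "
            "affected classes",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": row.astype(int),
    }


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix plus class-wise metrics and overall accuracy,
    all at timestep granularity; window-level majority-vote accuracy is
    included as a secondary figure."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    window_accuracy: float | None = None
    class_names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        payload = {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
        }
        if self.window_accuracy is not None:
            payload["window_accuracy"] = self.window_accuracy
        if self.class_names is not None:
            payload["class_names"] = list(self.class_names)
        return payload

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_table(self) -> str:
        names = self.class_names or tuple(
            f"class_{i}" for i in range(len(self.precision))
        )
        lines = [f"{'class':<16}{'precision':>10}{'recall':>10}{'f1':>10}{'support':>10}"]
        for i, name in enumerate(names):
            lines.append(
                f"{name:<16}{self.precision[i]:>10.4f}{self.recall[i]:>10.4f}"
                f"{self.f1[i]:>10.4f}{self.support[i]:>10d}"
            )
        lines.append(f"overall timestep accuracy: {self.accuracy:.4f}")
        return "\n".join(lines)


def evaluation_report(
    predictions: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    class_names: tuple[str, ...] | None = None,
) -> EvalReport:
    """Build the full report from per-timestep predictions and labels.

    2-D inputs of shape (n_windows, T) also yield the window-level
    majority-vote accuracy.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    window_acc = None
    if predictions.ndim == 2:
        maj_pred = _majority_vote(predictions, n_classes)
        maj_true = _majority_vote(labels, n_classes)
        window_acc = float((maj_pred == maj_true).mean()) if len(maj_pred) else 0.0
    cm = confusion_matrix(predictions, labels, n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        metrics = classwise_metrics(cm)
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return EvalReport(
        confusion=cm,
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        support=metrics["support"],
        accuracy=accuracy,
        window_accuracy=window_acc,
        class_names=class_names,
    )


def _majority_vote(tracks: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.stack([(tracks == k).sum(axis=1) for k in range(n_classes)], axis=1)
    return counts.argmax(axis=1)  # ties -> lowest class index


def attention_heatmap(
    records: list[AttentionRecord], layer: int, head: int
) -> np.ndarray:
    """Return (a copy of) the stored T x T attention matrix for one head."""
    for rec in records:
        if rec.layer == layer and rec.head == head:
            return rec.matrix.copy()
    available = sorted({(r.layer, r.head) for r in records})
    raise KeyError(
        f"no attention record for layer {layer}, head {head}; "
        f"available: {available}"
    )


def render_heatmap_png(matrix: np.ndarray, path, title: str = "") -> None:
    """Render a heatmap where higher weight is paler (grayscale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(matrix), cmap="gray", origin="upper")
    if title:
        ax.set_title(title)
    ax.set_xlabel("key timestep")
    ax.set_ylabel("query timestep")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def position_embedding_similarity(p: np.ndarray) -> np.ndarray:
    """T x T cosine similarities between position-embedding rows.

    All-zero rows have undefined direction; their similarities are reported
    as 0 with a warning. The result is symmetric with unit diagonal (for
    nonzero rows) and entries in [-1, 1].
    """
    p = np.asarray(p, dtype=float)
    norms = np.linalg.norm(p, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn(
            "position embedding has all-zero rows; their similarity is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    unit = p / safe[:, None]
    sim = unit @ unit.T
    np.clip(sim, -1.0, 1.0, out=sim)
    return sim


def attention_block_mass(
    matrix: np.ndarray, change_point: int | None = None
) -> dict[str, float]:
    """Mean attention mass within vs across window halves.

    ``ratio = within / cross``; ~1 for structureless (e.g. freshly
    initialized) attention, > 1 when the model segregates the two halves of
    an augmented pair window.
    """
    a = np.asarray(matrix, dtype=float)
    t = a.shape[0]
    m = change_point if change_point is not None else t // 2
    within = np.concatenate([a[:m, :m].ravel(), a[m:, m:].ravel()])
    cross = np.concatenate([a[:m, m:].ravel(), a[m:, :m].ravel()])
    w, c = float(within.mean()), float(cross.mean())
    return {"within": w, "cross": c, "ratio": w / c if c > 0 else np.inf}


def estimate_change_point(pred_labels: np.ndarray) -> int:
    """Best single change point for a predicted per-timestep label track.

    For every candidate split t (1..T-1) the track is modelled as two
    constant segments (each taking its majority label); the t maximizing
    the number of matched timesteps is returned (ties -> smallest t).
    """
    y = np.asarray(pred_labels, dtype=int)
    t_len = len(y)
    if t_len < 2:
        raise ValueError("need at least two timesteps")
    classes = np.unique(y)
    onehot = (y[:, None] == classes[None, :]).astype(int)
    prefix = np.vstack([np.zeros(len(classes), dtype=int), np.cumsum(onehot, axis=0)])
    total = prefix[-1]
    best_t, best_score = 1, -1
    for t in range(1, t_len):
        score = prefix[t].max() + (total - prefix[t]).max()
        if score > best_score:
            best_t, best_score = t, score
    return best_t
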