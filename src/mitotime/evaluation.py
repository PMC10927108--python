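"""Metrics and result artifacts.

Frame-to-frame accuracy is pooled over all evaluated frames (trace of the
confusion matrix over its total).  The confusion matrix follows the
true-rows / predicted-columns convention, and the displayed matrix is
row-normalized so the diagonal reads as per-class recall.  Precision,
recall and F-score use the 0/0 -> 0 convention.

Also here: the per-trajectory label matrix raster, PCA projection of
classifier-head embeddings, and threshold segmentation of the tracking
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "normalize_rows",
    "metrics",
    "metrics_from_labels",
    "EmbeddingProjection",
    "label_matrix",
    "plot_label_matrix",
    "embed_pca",
    "segment_by_threshold",
    "mask_iou",
    "THREE_CLASS_COLORS",
    "SIX_CLASS_COLORS",
]

# label-matrix palettes (stage index order)
THREE_CLASS_COLORS = ("green", "magenta", "red")
SIX_CLASS_COLORS = ("green", "yellow", "orange", "violet", "blue", "red")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with true class on rows and predicted class on columns."""

    counts: np.ndarray

    @property
    def n_class(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray

    @property
    def mean_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def mean_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def mean_f_score(self) -> float:
        return float(self.f_score.mean())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f_score": self.f_score.tolist(),
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "mean_f_score": self.mean_f_score,
        }


def confusion(true: np.ndarray, pred: np.ndarray, n_class: int) -> ConfusionMatrix:
    """Tally counts[i][j] = #frames with true stage i+1 predicted j+1."""
    true = np.asarray(true).ravel()
    pred = np.asarray(pred).ravel()
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    for name, arr in (("true", true), ("pred", pred)):
        if arr.size and (arr.min() < 1 or arr.max() > n_class):
            raise ValueError(f"{name} labels outside 1..{n_class}")
    counts = _sk_confusion(true, pred, labels=np.arange(1, n_class + 1))
    return ConfusionMatrix(counts)


def normalize_rows(cm: ConfusionMatrix | np.ndarray) -> np.ndarray:
    """Row-stochastic matrix; all-zero rows stay zero."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    counts = counts.astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy (pooled over frames) and per-class precision/recall/F."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    with np.errstate(invalid="ignore"):
        tp, fp, fn = cm.tp.astype(float), cm.fp.astype(float), cm.fn.astype(float)
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        pr = precision + recall
        f_score = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return MetricsReport(accuracy=float(cm.tp.sum() / cm.total),
                         precision=precision, recall=recall, f_score=f_score)


def metrics_from_labels(true, pred, n_class: int) -> MetricsReport:
    """Convenience wrapper (cross-checked against scikit-learn)."""
    return metrics(confusion(true, pred, n_class))


def sklearn_reference_metrics(true, pred, n_class: int):
    """Independent precision/recall/F from scikit-learn (used as an oracle
    in tests; not part of the metric pipeline)."""
    return precision_recall_fscore_support(
        true, pred, labels=np.arange(1, n_class + 1), zero_division=0)[:3]


# ---------------------------------------------------------------------------
# label matrices
# ---------------------------------------------------------------------------

def label_matrix(label_rows) -> pd.DataFrame:
    """Stack per-trajectory label vectors into a (trajectory x frame)
    matrix; rows must share a length."""
    rows = [np.asarray(r, dtype=int) for r in label_rows]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged trajectories: lengths {sorted(lengths)}")
    return pd.DataFrame(np.stack(rows))


def plot_label_matrix(df: pd.DataFrame, n_class: int, path=None, title=""):
    """Color-raster of a label matrix (one palette entry per stage)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    palette = THREE_CLASS_COLORS if n_class == 3 else SIX_CLASS_COLORS
    cmap = ListedColormap(palette[:n_class])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(df.to_numpy() - 1, cmap=cmap, vmin=-0.5, vmax=n_class - 0.5,
              aspect="auto", interpolation="nearest")
    ax.set_xlabel("frame")
    ax.set_ylabel("trajectory")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# embeddings and tracking output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingProjection:
    components: np.ndarray        # (n_samples, 3) PC scores
    labels: np.ndarray
    explained_variance_ratio: np.ndarray


def embed_pca(embeddings: np.ndarray, labels=None) -> EmbeddingProjection:
    """First three principal components of per-frame embedding vectors."""
    x = np.asarray(embeddings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise ValueError("need at least 4 embedding vectors")
    if x.shape[1] < 3:
        raise ValueError("embedding dimension must be >= 3")
    pca = PCA(n_components=3)
    scores = pca.fit_transform(x)
    labels = np.zeros(len(x), dtype=int) if labels is None else np.asarray(labels)
    return EmbeddingProjection(scores, labels, pca.explained_variance_ratio_)


def segment_by_threshold(track: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary center-cell segmentation from the tracking reconstruction:
    channel-mean intensity >= threshold."""
    track = np.asarray(track)
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if track.ndim == 3:       # (C, H, W)
        mean = track.mean(axis=0)
    elif track.ndim == 4:     # (T, C, H, W)
        mean = track.mean(axis=1)
    else:
        raise ValueError("expected (C,H,W) or (T,C,H,W) tracking output")
    return mean >= threshold


def mask_iou(pred: np.ndarray, true: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (empty/empty -> 1)."""
    pred, true = np.asarray(pred, bool), np.asarray(true, bool)
    union = (pred | true).sum()
    if union == 0:
        return 1.0
    return float((pred & true).sum() / union)
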