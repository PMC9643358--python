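"""Classification metrics: confusion matrix, per-class / macro / weighted
F1, one-vs-rest ROC AUC, and a thin 2-D embedding hook.

F1_k = 2 TP_k / (2 TP_k + FP_k + FN_k); macro F1 is the unweighted mean
over the K classes and weighted F1 the class-proportion-weighted sum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix", "MetricReport",
    "confusion", "f1_scores", "binary_auc", "roc_auc", "embed_2d",
]


@dataclass
class ConfusionMatrix:
    """counts[t][p]: rows are ground truth, columns the predicted class."""

    counts: np.ndarray

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    f1_per_class: np.ndarray
    macro_f1: float
    weighted_f1: float
    weights: np.ndarray
    auc_per_class: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        doc = {
            "f1_per_class": self.f1_per_class.tolist(),
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "weights": self.weights.tolist(),
        }
        if self.auc_per_class is not None:
            doc["auc_per_class"] = [
                None if np.isnan(v) else v for v in self.auc_per_class]
        text = json.dumps(doc, indent=2)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text


def confusion(labels, predictions, K: int = 7) -> ConfusionMatrix:
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    for name, arr in (("label", labels), ("prediction", predictions)):
        bad = np.where((arr < 0) | (arr >= K))[0]
        if bad.size:
            raise ValueError(f"{name} out of range 0..{K - 1} at index {bad[0]}")
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (labels, predictions), 1)
    return ConfusionMatrix(counts=counts)


def f1_scores(cm: ConfusionMatrix, weights=None) -> MetricReport:
    """Per-class F1 from the confusion matrix, plus macro and weighted F1.

    TP_i = cm[i][i], FP_i = column sum - TP_i, FN_i = row sum - TP_i;
    a 0/0 F1 (class never present nor predicted) is defined as 0 with a
    warning. Absent explicit weights, w_k are the true class proportions.
    """
    c = np.asarray(cm.counts, float)
    if c.size == 0 or c.sum() == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    if (denom == 0).any():
        warnings.warn("class with no true or predicted cases: F1 defined as 0")
    f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1.0), 0.0)
    if weights is None:
        w = c.sum(axis=1) / c.sum()
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    return MetricReport(f1_per_class=f1, macro_f1=float(f1.mean()),
                        weighted_f1=float((w * f1).sum()), weights=w)


def binary_auc(scores, positives) -> float:
    """One-vs-rest AUC via the rank (Mann-Whitney) statistic, ties averaged."""
    scores = np.asarray(scores, float)
    positives = np.asarray(positives).astype(bool)
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels) -> np.ndarray:
    """Per-class one-vs-rest AUC. scores: [n x K] class probabilities whose
    rows sum to 1; classes absent from the labels get NaN (undefined)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    K = scores.shape[1]
    out = np.empty(K)
    for k in range(K):
        out[k] = binary_auc(scores[:, k], labels == k)
    return out


def embed_2d(features, seed: int = 0) -> np.ndarray:
    """Neighborhood-preserving 2-D embedding (plumbing for cluster plots).

    t-SNE for reasonably sized inputs; principal components (with a fixed
    sign convention) for tiny ones where a perplexity cannot be chosen.
    Deterministic under a fixed seed.
    """
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 feature rows")
    n = X.shape[0]
    if n >= 10:
        from sklearn.manifold import TSNE
        perplexity = min(30.0, (n - 1) / 3.0)
        return TSNE(n_components=2, random_state=seed, init="pca",
                    perplexity=perplexity).fit_transform(X)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    vt = vt[:2]
    signs = np.sign(np.abs(vt).max(axis=1, keepdims=True).copy())
    for i in range(vt.shape[0]):  # fix sign by the largest-|.| component
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    coords = Xc @ vt.T
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords
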