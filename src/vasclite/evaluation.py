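"""Classification metrics, embedding export/projection, latency benchmark.

Metrics follow the four standard confusion-matrix formulas:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)          (sensitivity)
    F1        = 2 (precision * recall) / (precision + recall)

Per-class views are produced by swapping the positive class;
zero-denominator cases report 0 with a degeneracy flag instead of
raising.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.manifold import TSNE

from .models import EfficientNet

CLASS_NAMES = ("normal", "abnormal")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str = "normal"

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        other = [c for c in CLASS_NAMES if c != self.positive_class][0]
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp,
                               positive_class=other)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_label: int = 0,
                         positive_class: str = "normal") -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_label
        pos_p = y_pred == positive_label
        return cls(tp=int(np.sum(pos_t & pos_p)),
                   tn=int(np.sum(~pos_t & ~pos_p)),
                   fp=int(np.sum(~pos_t & pos_p)),
                   fn=int(np.sum(pos_t & ~pos_p)),
                   positive_class=positive_class)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def rounded(self, ndigits: int = 2) -> dict:
        return {"precision": round(self.precision, ndigits),
                "recall": round(self.recall, ndigits),
                "f1": round(self.f1, ndigits)}


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict  # class name -> ClassMetrics
    positive_class: str
    display_digits: int = 2

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_display": round(self.accuracy, self.display_digits),
            "positive_class": self.positive_class,
            "per_class": {
                name: {"precision": m.precision, "recall": m.recall,
                       "f1": m.f1, "degenerate": m.degenerate,
                       "display": m.rounded(self.display_digits)}
                for name, m in self.per_class.items()
            },
        }

    def write_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _one_view(cm: ConfusionMatrix) -> ClassMetrics:
    degenerate = False
    if cm.tp + cm.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = cm.tp / (cm.tp + cm.fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ClassMetrics(precision, recall, f1, degenerate)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Both per-class views plus overall accuracy."""
    if cm.n_samples == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.n_samples
    views = {cm.positive_class: _one_view(cm)}
    sw = cm.swapped()
    views[sw.positive_class] = _one_view(sw)
    return MetricsReport(accuracy=accuracy, per_class=views,
                         positive_class=cm.positive_class)


def predict(net: EfficientNet, x: np.ndarray, batch_size: int = 32):
    """Argmax class scores (ties go to the lower class index)."""
    preds = []
    for i in range(0, x.shape[0], batch_size):
        logits = net.forward(x[i:i + batch_size])
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def predict_and_tabulate(net: EfficientNet, x: np.ndarray, y: np.ndarray,
                         batch_size: int = 32):
    if net.num_classes != np.max(y) + 1 and np.max(y) >= net.num_classes:
        raise ValueError("label range exceeds model classes")
    y_pred = predict(net, x, batch_size)
    cm = ConfusionMatrix.from_predictions(y, y_pred, positive_label=0,
                                          positive_class=CLASS_NAMES[0])
    return y_pred, cm


def extract_embeddings(net: EfficientNet, x: np.ndarray,
                       batch_size: int = 32) -> np.ndarray:
    """Post-pooling, pre-FC feature vectors (n, embedding_dim)."""
    out = [net.features(x[i:i + batch_size])
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


def project_embeddings(matrix: np.ndarray, labels: np.ndarray,
                       perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE projection with pinned perplexity and seed."""
    n = matrix.shape[0]
    if n <= perplexity * 3:
        raise ValueError(
            f"n={n} too small for perplexity {perplexity} (need n > 3x)")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(np.asarray(matrix, dtype=np.float64))


@dataclass
class LatencyReport:
    mean_latency_ms: float
    device: str
    n_warmup: int
    n_timed: int
    batch_size: int = 1

    @property
    def fps(self) -> float:
        return 1000.0 / self.mean_latency_ms

    def to_dict(self) -> dict:
        return {
            "mean_latency_ms": self.mean_latency_ms,
            "fps": self.fps,
            "device": self.device,
            "n_warmup": self.n_warmup,
            "n_timed": self.n_timed,
            "batch_size": self.batch_size,
        }

    def write_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def benchmark_latency(net: EfficientNet, device: str = "cpu",
                      n_warmup: int = 20, n_timed: int = 200,
                      input_size: int = 224) -> LatencyReport:
    """Mean single-image (batch 1) forward time and its FPS reciprocal."""
    if device != "cpu":
        raise ValueError("only CPU inference is available")
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, size=(1, 3, input_size, input_size)).astype(np.float32)
    for _ in range(n_warmup):
        net.forward(x)
    t0 = time.perf_counter()
    for _ in range(n_timed):
        net.forward(x)
    elapsed = time.perf_counter() - t0
    return LatencyReport(mean_latency_ms=1000.0 * elapsed / n_timed,
                         device=device, n_warmup=n_warmup, n_timed=n_timed)
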