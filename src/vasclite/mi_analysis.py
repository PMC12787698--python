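"""Per-stage mutual information between pooled features and class labels.

For every MBConv stage the feature map of the stage's final repeat is
tapped twice — immediately before the SE gate (``pre_se``) and after it
(``post_se``) — pooled to a channel vector, and the dependence of each
channel on the binary label is estimated with the k-nearest-neighbour
MI estimator for continuous features / discrete targets. Comparing the
two series shows how much label information the SE recalibration adds
(or fails to add) at each depth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_selection import mutual_info_classif

from .models import EfficientNet

DEFAULT_NEIGHBORS = 3


@dataclass
class MIReport:
    stage_ids: list
    per_stage_mi_with_se: list
    per_stage_mi_without_se: list
    per_channel_with_se: list = field(default_factory=list)
    per_channel_without_se: list = field(default_factory=list)
    n_neighbors: int = DEFAULT_NEIGHBORS
    seed: int = 0

    def __post_init__(self):
        if not (len(self.stage_ids) == len(self.per_stage_mi_with_se)
                == len(self.per_stage_mi_without_se)):
            raise ValueError("stage/MI lists must be aligned")
        for v in (*self.per_stage_mi_with_se, *self.per_stage_mi_without_se):
            if v < 0:
                raise ValueError("MI values must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "stage_ids": self.stage_ids,
            "mi_with_se": self.per_stage_mi_with_se,
            "mi_without_se": self.per_stage_mi_without_se,
            "n_neighbors": self.n_neighbors,
            "seed": self.seed,
        }

    def write_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def write_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stage", "tap", "mi"])
            for sid, with_se, without in zip(
                    self.stage_ids, self.per_stage_mi_with_se,
                    self.per_stage_mi_without_se):
                w.writerow([sid, "post_se", f"{with_se:.6f}"])
                w.writerow([sid, "pre_se", f"{without:.6f}"])


def extract_stage_features(net: EfficientNet, images: np.ndarray,
                           stage_id: int, tap: str = "post_se") -> np.ndarray:
    """Pooled (n_samples, n_channels) features at one stage tap."""
    if images.ndim != 4 or images.shape[0] == 0:
        raise ValueError("images must be a nonempty N×3×H×W batch")
    fmap = net.forward_to_stage(images, stage_id, tap=tap)
    return fmap.mean(axis=(2, 3))


def estimate_mi(features: np.ndarray, labels: np.ndarray,
                n_neighbors: int = DEFAULT_NEIGHBORS, seed: int = 0,
                discrete: bool = False):
    """Per-channel MI (nats, clipped at 0) and the channel mean.

    Continuous features use the kNN estimator (k = ``n_neighbors``, seed
    pinned for the tie-breaking jitter); ``discrete=True`` switches to
    the plug-in contingency estimate. Returns ``(per_channel, mean)``.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValueError("features must be n_samples × n_channels")
    if not discrete and features.shape[0] < 10:
        raise ValueError("need at least 10 samples for the kNN estimator")
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    per_channel = mutual_info_classif(
        features, labels, discrete_features=discrete,
        n_neighbors=n_neighbors, random_state=seed)
    per_channel = np.clip(per_channel, 0.0, None)
    return per_channel, float(per_channel.mean())


def compare_se_contribution(net: EfficientNet, images: np.ndarray,
                            labels: np.ndarray,
                            n_neighbors: int = DEFAULT_NEIGHBORS,
                            seed: int = 0,
                            batch_size: int = 32) -> MIReport:
    """Per-stage MI with and without SE gating, over all stages."""
    stage_ids = [spec.stage_index for spec in net.stage_specs]
    with_se, without_se = [], []
    chan_with, chan_without = [], []
    for sid in stage_ids:
        feats = {}
        for tap in ("pre_se", "post_se"):
            chunks = [
                extract_stage_features(net, images[i:i + batch_size], sid, tap)
                for i in range(0, images.shape[0], batch_size)
            ]
            feats[tap] = np.concatenate(chunks, axis=0)
        pc_post, mean_post = estimate_mi(feats["post_se"], labels,
                                         n_neighbors, seed)
        pc_pre, mean_pre = estimate_mi(feats["pre_se"], labels,
                                       n_neighbors, seed)
        with_se.append(mean_post)
        without_se.append(mean_pre)
        chan_with.append(pc_post.tolist())
        chan_without.append(pc_pre.tolist())
    return MIReport(stage_ids, with_se, without_se, chan_with, chan_without,
                    n_neighbors=n_neighbors, seed=seed)
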