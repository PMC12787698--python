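"""Dataset construction: channel extraction, preprocessing, class-targeted
augmentation, Gaussian-noise expansion, and split/manifest bookkeeping.

Stages mirror the study design: an imbalanced original set (normal
minority), a 10-transform geometric augmentation applied only to normal
training images, and a noise-expansion pass over the training pool.
Derived images always inherit their source's split, so validation and
test sets never receive derivatives.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage import transform as sktransform

CLASSES = ("normal", "abnormal")
SPLITS = ("train", "val", "test")

#: Study split layout: per-split (normal, abnormal) counts.
STUDY_SPLIT_COUNTS = {
    "train": {"normal": 80, "abnormal": 884},
    "val": {"normal": 21, "abnormal": 21},
    "test": {"normal": 68, "abnormal": 68},
}

#: Noise-expansion additions implied by the study's stage table.
STUDY_NOISE_COUNTS = {"normal": 272, "abnormal": 169}


@dataclass
class ImageRecord:
    """One image with provenance through the pipeline."""

    uid: str
    image: np.ndarray  # float32 in [0, 1], H×W
    label: int  # 0 = normal, 1 = abnormal
    split: str
    source: str = ""
    transforms: tuple = ()
    noise_sigma: float | None = None

    @property
    def class_name(self) -> str:
        return CLASSES[self.label]


@dataclass
class DatasetManifest:
    stage: str
    normal_count: int
    abnormal_count: int
    split_counts: dict
    provenance: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.normal_count + self.abnormal_count

    @classmethod
    def from_records(cls, stage: str, records: list) -> "DatasetManifest":
        split_counts = {s: {c: 0 for c in CLASSES} for s in SPLITS}
        n_by_class = {c: 0 for c in CLASSES}
        prov = []
        for r in records:
            n_by_class[r.class_name] += 1
            split_counts[r.split][r.class_name] += 1
            prov.append({
                "uid": r.uid,
                "class": r.class_name,
                "split": r.split,
                "source": r.source,
                "transforms": "|".join(r.transforms),
                "noise_sigma": "" if r.noise_sigma is None
                               else f"{r.noise_sigma:.6f}",
            })
        m = cls(stage, n_by_class["normal"], n_by_class["abnormal"],
                split_counts, prov)
        m.validate()
        return m

    def validate(self):
        for c, n in (("normal", self.normal_count),
                     ("abnormal", self.abnormal_count)):
            by_split = sum(self.split_counts[s][c] for s in SPLITS)
            if by_split != n:
                raise ValueError(
                    f"split counts for {c} sum to {by_split}, expected {n}")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "normal_count": self.normal_count,
            "abnormal_count": self.abnormal_count,
            "total": self.total,
            "split_counts": self.split_counts,
        }

    def write_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def write_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=[
                "uid", "class", "split", "source", "transforms", "noise_sigma"])
            w.writeheader()
            w.writerows(self.provenance)


@dataclass(frozen=True)
class AugmentationPlan:
    """10 geometric transforms per source image, normal-train only."""

    flips: tuple = ("horizontal", "vertical")
    rotation_angles_deg: tuple = (15, 30, 60, 90, 180, 270)
    zoom_ratios: tuple = (0.05, 0.10)
    target_class: str = "normal"
    target_split: str = "train"

    @property
    def size(self) -> int:
        return (len(self.flips) + len(self.rotation_angles_deg)
                + len(self.zoom_ratios))

    def __post_init__(self):
        if self.target_split != "train":
            raise ValueError(
                "augmentation may target only the training split")


@dataclass(frozen=True)
class NoiseSpec:
    mean: float = 0.0
    sigma_range: tuple = (0.02, 0.06)
    added_per_class: dict = field(
        default_factory=lambda: dict(STUDY_NOISE_COUNTS))

    def __post_init__(self):
        lo, hi = self.sigma_range
        if hi < lo:
            raise ValueError("sigma_range is inverted")


# -- operations ----------------------------------------------------------

def extract_vessel_channel(tiff_path, channel_index: int) -> np.ndarray:
    """One 2-D plane from a multichannel TIFF, bit depth preserved."""
    path = Path(tiff_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        if channel_index != 0:
            raise IndexError(
                f"single-channel image has no channel {channel_index}")
        return arr
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D TIFF, got shape {arr.shape}")
    # channel axis: leading (C,H,W) preferred, else trailing (H,W,C)
    if arr.shape[0] <= 16:
        n_ch, grab = arr.shape[0], lambda i: arr[i]
    elif arr.shape[-1] <= 16:
        n_ch, grab = arr.shape[-1], lambda i: arr[..., i]
    else:
        raise ValueError(f"cannot locate channel axis in shape {arr.shape}")
    if not 0 <= channel_index < n_ch:
        raise IndexError(
            f"channel {channel_index} out of range for {n_ch}-channel image")
    return grab(channel_index)


def _to_unit(image: np.ndarray) -> np.ndarray:
    """Map native full-scale range to [0, 1]."""
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    if image.dtype == np.uint16:
        return image.astype(np.float32) / 65535.0
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float32) / float(np.iinfo(image.dtype).max)
    return image.astype(np.float32)


def preprocess(image: np.ndarray, size: int = 224) -> np.ndarray:
    """2-D image -> 3×size×size float32 tensor in [−1, 1].

    Bilinear resize, grayscale replicated to three channels, intensities
    mapped linearly from the native full-scale range.
    """
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D intensity image")
    unit = _to_unit(image)
    if unit.shape != (size, size):
        unit = sktransform.resize(unit, (size, size), order=1, mode="edge",
                                  anti_aliasing=False,
                                  preserve_range=True).astype(np.float32)
    tensor = unit * 2.0 - 1.0
    return np.repeat(tensor[None], 3, axis=0)


def preprocess_batch(images, size: int = 224) -> np.ndarray:
    return np.stack([preprocess(im, size) for im in images])


def _zoom_center(image: np.ndarray, ratio: float) -> np.ndarray:
    """Upscale by (1+ratio), center-crop back to the original size."""
    h, w = image.shape
    up = sktransform.rescale(image, 1.0 + ratio, order=1,
                             preserve_range=True, anti_aliasing=False)
    r0 = (up.shape[0] - h) // 2
    c0 = (up.shape[1] - w) // 2
    return up[r0:r0 + h, c0:c0 + w].astype(image.dtype)


def transform_image(image: np.ndarray, name: str) -> np.ndarray:
    if name == "hflip":
        return image[:, ::-1].copy()
    if name == "vflip":
        return image[::-1].copy()
    if name.startswith("rot"):
        angle = float(name[3:])
        return sktransform.rotate(image, angle, resize=False, order=1,
                                  mode="constant", cval=0.0,
                                  preserve_range=True).astype(image.dtype)
    if name.startswith("zoom"):
        return _zoom_center(image, float(name[4:]) / 100.0)
    raise ValueError(f"unknown transform {name!r}")


def plan_transform_names(plan: AugmentationPlan) -> list:
    names = []
    for f in plan.flips:
        names.append("hflip" if f == "horizontal" else "vflip")
    names += [f"rot{a}" for a in plan.rotation_angles_deg]
    names += [f"zoom{int(round(z * 100))}" for z in plan.zoom_ratios]
    return names


def augment(records: list, plan: AugmentationPlan,
            rng: np.random.Generator | None = None):
    """Emit plan.size transformed copies of each targeted image.

    Only images matching the plan's class+split selector are expanded;
    originals are retained. Returns ``(all_records, manifest)``.
    """
    if not records:
        raise ValueError("no input records")
    names = plan_transform_names(plan)
    target_label = CLASSES.index(plan.target_class)
    out = list(records)
    for rec in records:
        if rec.label != target_label or rec.split != plan.target_split:
            continue
        for name in names:
            out.append(ImageRecord(
                uid=f"{rec.uid}+{name}",
                image=transform_image(rec.image, name),
                label=rec.label, split=rec.split, source=rec.uid,
                transforms=rec.transforms + (name,)))
    return out, DatasetManifest.from_records("after_augmentation", out)


def add_noise(records: list, spec: NoiseSpec, rng: np.random.Generator):
    """Noise-expand the training pool per the configured class counts.

    Source images are drawn (seeded, without replacement where possible)
    from the training split of each class; each copy gets i.i.d.
    zero-mean Gaussian noise with σ ~ U[sigma_range] on [0, 1]
    intensities, clipped back to [0, 1].
    """
    out = list(records)
    lo, hi = spec.sigma_range
    for class_name, n_added in spec.added_per_class.items():
        label = CLASSES.index(class_name)
        pool = [r for r in records if r.label == label and r.split == "train"]
        if not pool:
            if n_added:
                raise ValueError(f"no training sources for class {class_name}")
            continue
        if n_added <= len(pool):
            idx = rng.choice(len(pool), size=n_added, replace=False)
        else:
            idx = rng.choice(len(pool), size=n_added, replace=True)
        for k, i in enumerate(idx):
            src = pool[int(i)]
            sigma = float(rng.uniform(lo, hi))
            noisy = src.image + rng.normal(spec.mean, sigma,
                                           size=src.image.shape)
            out.append(ImageRecord(
                uid=f"{src.uid}+noise{k}",
                image=np.clip(noisy, 0.0, 1.0).astype(np.float32),
                label=src.label, split=src.split, source=src.uid,
                transforms=src.transforms + ("noise",),
                noise_sigma=sigma))
    return out, DatasetManifest.from_records("after_noise", out)


def build_split(records: list, split_counts: dict, seed: int):
    """Deterministic seeded split assignment with configured counts.

    ``split_counts``: {split: {class_name: count}}. Returns records with
    the ``split`` field assigned plus the original-stage manifest.
    """
    rng = np.random.default_rng(seed)
    by_class = {c: [r for r in records if r.class_name == c] for c in CLASSES}
    for c, pool in by_class.items():
        need = sum(split_counts[s].get(c, 0) for s in split_counts)
        if need > len(pool):
            raise ValueError(
                f"split needs {need} {c} images but only {len(pool)} available")
    assigned = []
    for c, pool in by_class.items():
        order = rng.permutation(len(pool))
        cursor = 0
        for s in SPLITS:
            n = split_counts.get(s, {}).get(c, 0)
            for i in order[cursor:cursor + n]:
                assigned.append(replace(pool[int(i)], split=s))
            cursor += n
        for i in order[cursor:]:  # leftovers stay in train
            assigned.append(replace(pool[int(i)], split="train"))
    return assigned, DatasetManifest.from_records("original", assigned)


def records_to_arrays(records: list, size: int = 224, split: str | None = None):
    """Preprocess records to (X, y) model tensors, optionally one split."""
    chosen = [r for r in records if split is None or r.split == split]
    x = preprocess_batch([r.image for r in chosen], size)
    y = np.array([r.label for r in chosen])
    return x, y
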