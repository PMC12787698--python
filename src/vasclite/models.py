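"""EfficientNet-B0/B1/B2 backbones and their lightweight variants.

Four variants of each base are supported:

============  ==========  ========
name          activation  SE block
============  ==========  ========
original      SiLU        yes
modified1     ReLU        yes
modified2     SiLU        no (identity DummySE)
modified3     ReLU        no (identity DummySE)
============  ==========  ========

Removing SE strips its two FC layers from every MBConv repeat; swapping
the activation leaves parameter counts untouched. Channel widths scale
by ``width_mult`` with rounding to the nearest multiple of 8 (never
dropping below 90% of the unrounded value); per-stage repeat counts
scale by ``ceil(depth_mult * repeats)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

VARIANTS = ("original", "modified1", "modified2", "modified3")

#: (activation, use_se) per variant
_VARIANT_TABLE = {
    "original": ("silu", True),
    "modified1": ("relu", True),
    "modified2": ("silu", False),
    "modified3": ("relu", False),
}


@dataclass(frozen=True)
class ScalingConfig:
    """Compound-scaling coefficients of one base model."""

    base_name: str
    width_mult: float
    depth_mult: float
    input_resolution: int = 224
    classifier_dropout: float = 0.2

    def __post_init__(self):
        if self.width_mult < 1.0 or self.depth_mult < 1.0:
            raise ValueError("width/depth multipliers must be >= 1.0")


#: All three bases share the 224x224 input the classifier is trained at.
SCALINGS = {
    "B0": ScalingConfig("B0", 1.0, 1.0),
    "B1": ScalingConfig("B1", 1.0, 1.1),
    "B2": ScalingConfig("B2", 1.1, 1.2),
}


@dataclass(frozen=True)
class BlockSpec:
    """Layout of one MBConv stage before compound scaling."""

    stage_index: int
    kernel_size: int
    stride: int
    expand_ratio: int
    in_channels: int
    out_channels: int
    repeats: int
    se_ratio: float | None = 0.25

    def __post_init__(self):
        if self.expand_ratio not in (1, 6):
            raise ValueError("expand_ratio must be 1 or 6")
        if self.kernel_size not in (3, 5):
            raise ValueError("kernel_size must be 3 or 5")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


#: Seven-stage B0 layout: (stage, k, stride, expand, c_in, c_out, repeats)
B0_STAGES = (
    BlockSpec(1, 3, 1, 1, 32, 16, 1),
    BlockSpec(2, 3, 2, 6, 16, 24, 2),
    BlockSpec(3, 5, 2, 6, 24, 40, 2),
    BlockSpec(4, 3, 2, 6, 40, 80, 3),
    BlockSpec(5, 5, 1, 6, 80, 112, 3),
    BlockSpec(6, 5, 2, 6, 112, 192, 4),
    BlockSpec(7, 3, 1, 6, 192, 320, 1),
)

STEM_CHANNELS = 32
HEAD_CHANNELS = 1280


@dataclass(frozen=True)
class SEConfig:
    """Squeeze-and-excitation geometry for one MBConv block."""

    present: bool = True
    reduction_ratio: int = 4

    def squeezed_width(self, block_in_channels: int) -> int:
        return max(1, block_in_channels // self.reduction_ratio)


@dataclass(frozen=True)
class VariantConfig:
    name: str
    activation: str
    use_se: bool

    @classmethod
    def from_name(cls, name: str) -> "VariantConfig":
        key = name.lower().replace(" ", "").replace("_", "")
        if key not in _VARIANT_TABLE:
            raise ValueError(
                f"unknown variant {name!r}; expected one of {VARIANTS}")
        act, use_se = _VARIANT_TABLE[key]
        return cls(key, act, use_se)


@dataclass
class ParameterReport:
    """Trainable-parameter, activation-site and size accounting."""

    base: str
    variant: str
    num_classes: int
    total_trainable_params: int
    params_per_stage: dict
    activation_sites: int
    buffer_entries: int
    serialized_size_bytes: int

    @property
    def params_millions(self) -> float:
        return round(self.total_trainable_params / 1e6, 1)

    @property
    def size_mb(self) -> float:
        return round(self.serialized_size_bytes / 1e6, 1)

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "variant": self.variant,
            "num_classes": self.num_classes,
            "total_trainable_params": self.total_trainable_params,
            "params_millions": self.params_millions,
            "params_per_stage": self.params_per_stage,
            "activation_sites": self.activation_sites,
            "buffer_entries": self.buffer_entries,
            "serialized_size_bytes": self.serialized_size_bytes,
            "size_mb": self.size_mb,
        }


def round_channels(channels: int, width_mult: float, divisor: int = 8) -> int:
    """Scale and round to the nearest multiple of 8, floored at 90%."""
    scaled = channels * width_mult
    rounded = max(divisor, int(scaled + divisor / 2) // divisor * divisor)
    if rounded < 0.9 * scaled:
        rounded += divisor
    return rounded


def round_repeats(repeats: int, depth_mult: float) -> int:
    return int(math.ceil(depth_mult * repeats))


def scaled_stages(scaling: ScalingConfig) -> list[BlockSpec]:
    """Apply compound scaling to the B0 layout."""
    out = []
    c_in = round_channels(STEM_CHANNELS, scaling.width_mult)
    for spec in B0_STAGES:
        c_out = round_channels(spec.out_channels, scaling.width_mult)
        out.append(BlockSpec(
            spec.stage_index, spec.kernel_size, spec.stride, spec.expand_ratio,
            c_in, c_out, round_repeats(spec.repeats, scaling.depth_mult),
            spec.se_ratio))
        c_in = c_out
    return out


def activation(kind: str, x):
    """Elementwise SiLU x/(1+e^-x) or ReLU max(0, x)."""
    x = np.asarray(x, dtype=np.float64)
    if kind == "silu":
        return x / (1.0 + np.exp(-x))
    if kind == "relu":
        return np.maximum(x, 0.0)
    raise ValueError(f"unknown activation kind: {kind!r}")


def se_forward(feature_map: np.ndarray, se: SEConfig, weights: dict | None = None,
               act_kind: str = "silu") -> np.ndarray:
    """Apply SE gating to a C×H×W (or N×C×H×W) map; identity when absent."""
    if not se.present:
        return feature_map
    if weights is None:
        raise ValueError("weights required when SE is present")
    single = feature_map.ndim == 3
    x = feature_map[None] if single else feature_map
    c = x.shape[1]
    if weights["w1"].shape[1] != c or weights["w2"].shape[0] != c:
        raise ValueError(
            f"channel mismatch: map has {c} channels, weights expect "
            f"{weights['w1'].shape[1]}")
    mod = nn.SqueezeExcite(c, weights["w1"].shape[0], act_kind)
    mod.w1.data = np.asarray(weights["w1"], dtype=np.float32)
    mod.b1.data = np.asarray(weights["b1"], dtype=np.float32)
    mod.w2.data = np.asarray(weights["w2"], dtype=np.float32)
    mod.b2.data = np.asarray(weights["b2"], dtype=np.float32)
    out = mod.forward(x.astype(np.float32))
    return out[0] if single else out


class MBConv(nn.Module):
    """Inverted bottleneck: expand -> depthwise -> SE/DummySE -> project."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 expand_ratio: int, variant: VariantConfig, se: SEConfig,
                 rng: np.random.Generator):
        self.c_in = c_in
        self.c_out = c_out
        self.stride = stride
        self.expand_ratio = expand_ratio
        self.use_residual = stride == 1 and c_in == c_out
        c_mid = c_in * expand_ratio
        if expand_ratio != 1:
            self.expand_conv = nn.Conv2d(c_in, c_mid, 1, rng=rng)
            self.expand_bn = nn.BatchNorm2d(c_mid)
            self.expand_act = nn.Activation(variant.activation)
        self.dw_conv = nn.DepthwiseConv2d(c_mid, kernel, stride, rng=rng)
        self.dw_bn = nn.BatchNorm2d(c_mid)
        self.dw_act = nn.Activation(variant.activation)
        if variant.use_se and se.present:
            self.se = nn.SqueezeExcite(
                c_mid, se.squeezed_width(c_in), variant.activation, rng=rng)
        else:
            self.se = nn.DummySE()
        self.project_conv = nn.Conv2d(c_mid, c_out, 1, rng=rng)
        self.project_bn = nn.BatchNorm2d(c_out)

    def forward(self, x, training: bool = False, capture: bool = False):
        h = x
        if self.expand_ratio != 1:
            h = self.expand_act.forward(
                self.expand_bn.forward(
                    self.expand_conv.forward(h, training), training), training)
        h = self.dw_act.forward(
            self.dw_bn.forward(self.dw_conv.forward(h, training), training),
            training)
        if capture:
            self.se_input = h
        h = self.se.forward(h, training)
        if capture:
            self.se_output = h
        h = self.project_bn.forward(self.project_conv.forward(h, training),
                                    training)
        if self.use_residual:
            h = h + x
        return h

    def backward(self, dout):
        dres = dout if self.use_residual else None
        d = self.project_conv.backward(self.project_bn.backward(dout))
        d = self.se.backward(d)
        d = self.dw_conv.backward(self.dw_bn.backward(self.dw_act.backward(d)))
        if self.expand_ratio != 1:
            d = self.expand_conv.backward(
                self.expand_bn.backward(self.expand_act.backward(d)))
        if dres is not None:
            d = d + dres
        return d


class EfficientNet(nn.Module):
    """Stem -> 7 MBConv stages -> 1x1 conv head -> GAP -> dropout -> FC."""

    def __init__(self, scaling: ScalingConfig, variant: VariantConfig,
                 num_classes: int = 2, seed: int = 0):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        rng = np.random.default_rng(seed)
        self.scaling = scaling
        self.variant = variant
        self.num_classes = num_classes
        self.seed = seed
        self.stage_specs = scaled_stages(scaling)

        stem_c = round_channels(STEM_CHANNELS, scaling.width_mult)
        self.stem_conv = nn.Conv2d(3, stem_c, 3, stride=2, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_c)
        self.stem_act = nn.Activation(variant.activation)

        se = SEConfig(present=variant.use_se)
        stages = []
        for spec in self.stage_specs:
            blocks = nn.ModuleList()
            c_in = spec.in_channels
            for rep in range(spec.repeats):
                stride = spec.stride if rep == 0 else 1
                blocks.append(MBConv(c_in, spec.out_channels, spec.kernel_size,
                                     stride, spec.expand_ratio, variant, se, rng))
                c_in = spec.out_channels
            stages.append(blocks)
        self.stages = nn.ModuleList(
            [_Stage(blocks) for blocks in stages])

        head_c = round_channels(HEAD_CHANNELS, scaling.width_mult)
        self.head_conv = nn.Conv2d(self.stage_specs[-1].out_channels, head_c, 1,
                                   rng=rng)
        self.head_bn = nn.BatchNorm2d(head_c)
        self.head_act = nn.Activation(variant.activation)
        self.pool = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(scaling.classifier_dropout,
                                  rng=np.random.default_rng(rng.integers(2**31)))
        self.fc = nn.Linear(head_c, num_classes, rng=rng)
        self.embedding_dim = head_c

    # -- forward/backward ------------------------------------------------
    def forward(self, x, training: bool = False):
        h = self.stem_act.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, training), training),
            training)
        for stage in self.stages:
            h = stage.forward(h, training)
        return self.head(h, training)

    def features(self, x, training: bool = False):
        """Post-pooling pre-FC embedding (N, embedding_dim)."""
        h = self.stem_act.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, training), training),
            training)
        for stage in self.stages:
            h = stage.forward(h, training)
        h = self.head_act.forward(
            self.head_bn.forward(self.head_conv.forward(h, training), training),
            training)
        return self.pool.forward(h, training)

    def head(self, h, training: bool = False):
        h = self.head_act.forward(
            self.head_bn.forward(self.head_conv.forward(h, training), training),
            training)
        h = self.pool.forward(h, training)
        h = self.dropout.forward(h, training)
        return self.fc.forward(h, training)

    def backward(self, dlogits):
        d = self.fc.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.pool.backward(d)
        d = self.head_conv.backward(
            self.head_bn.backward(self.head_act.backward(d)))
        for stage in reversed(list(self.stages)):
            d = stage.backward(d)
        return self.stem_conv.backward(
            self.stem_bn.backward(self.stem_act.backward(d)))

    # -- stage taps for the MI analysis ----------------------------------
    def forward_to_stage(self, x, stage_index: int, tap: str = "post_se"):
        """Run inference to the final repeat of ``stage_index`` (1-based).

        Returns the feature map tapped either after SE gating (post_se)
        or immediately before it (pre_se) in that repeat.
        """
        if tap not in ("pre_se", "post_se"):
            raise ValueError(f"unknown tap {tap!r}")
        if not 1 <= stage_index <= len(self.stage_specs):
            raise ValueError(f"invalid stage index {stage_index}")
        h = self.stem_act.forward(self.stem_bn.forward(self.stem_conv.forward(x)))
        for i, stage in enumerate(self.stages, start=1):
            if i < stage_index:
                h = stage.forward(h)
                continue
            blocks = list(stage.blocks)
            for block in blocks[:-1]:
                h = block.forward(h)
            last = blocks[-1]
            last.forward(h, capture=True)
            return last.se_input if tap == "pre_se" else last.se_output
        raise AssertionError("unreachable")


class _Stage(nn.Module):
    def __init__(self, blocks: nn.ModuleList):
        self.blocks = blocks

    def forward(self, x, training: bool = False):
        for b in self.blocks:
            x = b.forward(x, training)
        return x

    def backward(self, dout):
        for b in reversed(list(self.blocks)):
            dout = b.backward(dout)
        return dout


def build_model(scaling, variant, num_classes: int = 2,
                seed: int = 0) -> EfficientNet:
    """Construct a base/variant network with seeded initialization."""
    if isinstance(scaling, str):
        if scaling not in SCALINGS:
            raise ValueError(
                f"unknown base {scaling!r}; registered: {sorted(SCALINGS)}")
        scaling = SCALINGS[scaling]
    if isinstance(variant, str):
        variant = VariantConfig.from_name(variant)
    return EfficientNet(scaling, variant, num_classes=num_classes, seed=seed)


def count_activation_sites(scaling, variant) -> int:
    """Number of main-activation application points in the built graph.

    SE internal activations count; the sigmoid excitation gate does not.
    """
    net = build_model(scaling, variant, num_classes=2, seed=0)
    return count_activation_sites_of(net)


def count_activation_sites_of(net: EfficientNet) -> int:
    sites = 0
    for mod in net.modules():
        if isinstance(mod, nn.Activation):
            sites += 1
        elif isinstance(mod, nn.SqueezeExcite):
            sites += 1
    return sites


def _stage_param_groups(net: EfficientNet) -> dict:
    groups = {"stem": [net.stem_conv, net.stem_bn]}
    for spec, stage in zip(net.stage_specs, net.stages):
        groups[f"stage{spec.stage_index}"] = list(stage.blocks)
    groups["head"] = [net.head_conv, net.head_bn, net.fc]
    return groups


def parameter_report(net: EfficientNet) -> ParameterReport:
    """Count trainable tensors per stage and the float32 payload size."""
    per_stage = {}
    for name, mods in _stage_param_groups(net).items():
        per_stage[name] = int(sum(m.num_parameters() for m in mods))
    total = int(net.num_parameters())
    assert total == sum(per_stage.values())
    buffers = int(sum(b.size for _, b in net.named_buffers()))
    return ParameterReport(
        base=net.scaling.base_name,
        variant=net.variant.name,
        num_classes=net.num_classes,
        total_trainable_params=total,
        params_per_stage=per_stage,
        activation_sites=count_activation_sites_of(net),
        buffer_entries=buffers,
        serialized_size_bytes=4 * (total + buffers),
    )


# -- checkpoint I/O ------------------------------------------------------

def save_checkpoint(net: EfficientNet, path: str | Path):
    """Weight map as .npz plus a JSON sidecar describing the build."""
    path = Path(path)
    arrays = {f"param/{n}": p.data for n, p in net.named_parameters()}
    arrays.update({f"buffer/{n}": b for n, b in net.named_buffers()})
    np.savez(path, **arrays)
    meta = {
        "base": net.scaling.base_name,
        "variant": net.variant.name,
        "num_classes": net.num_classes,
        "seed": net.seed,
        "param_count": int(net.num_parameters()),
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_checkpoint(path: str | Path) -> EfficientNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    net = build_model(meta["base"], meta["variant"],
                      num_classes=meta["num_classes"], seed=meta["seed"])
    with np.load(path) as data:
        params = dict(net.named_parameters())
        for key in data.files:
            kind, name = key.split("/", 1)
            if kind == "param":
                params[name].data = data[key]
            else:
                _assign_buffer(net, name, data[key])
    return net


def _assign_buffer(net: nn.Module, dotted: str, value: np.ndarray):
    parts = dotted.split(".")
    obj = net
    for part in parts[:-1]:
        obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
    obj._set_buffer(parts[-1], value)
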