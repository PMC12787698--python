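"""Backbone zoo: parameter accounting, activation census, SE behavior."""

import math

import numpy as np
import pytest

from vasclite import models, nn
from vasclite.models import (
    SCALINGS,
    SEConfig,
    VariantConfig,
    build_model,
    count_activation_sites,
    parameter_report,
    se_forward,
)

# ---------------------------------------------------------------------------
# Independent oracle: enumerate tensor shapes from the architecture
# arithmetic alone, never touching the network implementation.
# ---------------------------------------------------------------------------

B0_LAYOUT = [  # (kernel, stride, expand, out_channels, repeats)
    (3, 1, 1, 16, 1),
    (3, 2, 6, 24, 2),
    (5, 2, 6, 40, 2),
    (3, 2, 6, 80, 3),
    (5, 1, 6, 112, 3),
    (5, 2, 6, 192, 4),
    (3, 1, 6, 320, 1),
]


def oracle_round_channels(c, width, divisor=8):
    scaled = c * width
    rounded = max(divisor, int(scaled + divisor / 2) // divisor * divisor)
    if rounded < 0.9 * scaled:
        rounded += divisor
    return rounded


def oracle_param_count(width, depth, use_se, num_classes):
    rc = lambda c: oracle_round_channels(c, width)
    total = 0
    c_in = rc(32)
    total += 3 * 3 * 3 * c_in + 2 * c_in  # stem conv + bn affine
    for k, s, e, c_out, reps in B0_LAYOUT:
        c_out = rc(c_out)
        for _ in range(math.ceil(depth * reps)):
            c_mid = c_in * e
            if e != 1:
                total += c_in * c_mid + 2 * c_mid  # expand 1x1 + bn
            total += k * k * c_mid + 2 * c_mid  # depthwise + bn
            if use_se:
                sq = max(1, c_in // 4)  # squeezed from block input channels
                total += c_mid * sq + sq + sq * c_mid + c_mid  # two FCs w/ bias
            total += c_mid * c_out + 2 * c_out  # project 1x1 + bn
            c_in = c_out
    head = rc(1280)
    total += c_in * head + 2 * head  # head conv + bn
    total += head * num_classes + num_classes  # FC with bias
    return total


def oracle_activation_sites(depth, use_se):
    sites = 2  # stem + head
    for _, _, e, _, reps in B0_LAYOUT:
        for _ in range(math.ceil(depth * reps)):
            sites += 1 if e == 1 else 2  # depthwise (+ expansion)
            if use_se:
                sites += 1  # SE internal activation
    return sites


MULTS = {"B0": (1.0, 1.0), "B1": (1.0, 1.1), "B2": (1.1, 1.2)}


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("base", ["B0", "B1", "B2"])
@pytest.mark.parametrize("use_se", [True, False])
def test_param_count_matches_shape_enumeration_oracle(base, use_se):
    width, depth = MULTS[base]
    variant = "original" if use_se else "modified2"
    net = build_model(base, variant, num_classes=2, seed=0)
    assert net.num_parameters() == oracle_param_count(width, depth, use_se, 2)


def test_b0_printed_millions():
    orig = parameter_report(build_model("B0", "original", 2))
    mod3 = parameter_report(build_model("B0", "modified3", 2))
    assert orig.params_millions == 4.0
    assert mod3.params_millions == 3.4
    reduction = 1 - mod3.total_trainable_params / orig.total_trainable_params
    assert 0.13 < reduction < 0.18


@pytest.mark.parametrize("base,expect_se,expect_nose",
                         [("B0", 4.0, 3.4), ("B1", 6.5, 5.4), ("B2", 7.7, 6.4)])
def test_all_bases_printed_millions(base, expect_se, expect_nose):
    assert parameter_report(
        build_model(base, "original", 2)).params_millions == expect_se
    assert parameter_report(
        build_model(base, "modified2", 2)).params_millions == expect_nose


@pytest.mark.parametrize("base", ["B0", "B1", "B2"])
def test_parameter_identities_across_variants(base):
    counts = {v: build_model(base, v, 2).num_parameters()
              for v in models.VARIANTS}
    assert counts["modified1"] == counts["original"]
    assert counts["modified3"] == counts["modified2"]
    assert counts["modified2"] < counts["original"]


def test_per_stage_counts_sum_to_total(b0_original):
    rep = parameter_report(b0_original)
    assert sum(rep.params_per_stage.values()) == rep.total_trainable_params


def test_serialized_size_shrinks_without_se():
    orig = parameter_report(build_model("B0", "original", 2))
    mod2 = parameter_report(build_model("B0", "modified2", 2))
    assert mod2.serialized_size_bytes < orig.serialized_size_bytes
    assert orig.serialized_size_bytes == 4 * (orig.total_trainable_params
                                              + orig.buffer_entries)


# ---------------------------------------------------------------------------
# activation census
# ---------------------------------------------------------------------------

def test_b0_original_counts_49_sites():
    assert count_activation_sites("B0", "original") == 49


def test_b0_modified2_counts_33_sites():
    # 49 minus one SE-internal site per MBConv repeat (16 repeats)
    assert count_activation_sites("B0", "modified2") == 33
    assert count_activation_sites("B0", "modified2") == oracle_activation_sites(1.0, False)


@pytest.mark.parametrize("base", ["B0", "B1", "B2"])
def test_census_against_oracle_and_substitution_identity(base):
    _, depth = MULTS[base]
    for use_se, variants in ((True, ("original", "modified1")),
                             (False, ("modified2", "modified3"))):
        expected = oracle_activation_sites(depth, use_se)
        for v in variants:
            assert count_activation_sites(base, v) == expected


@pytest.mark.parametrize("base", ["B0", "B1", "B2"])
def test_census_gap_equals_repeat_count(base):
    net = build_model(base, "original", 2)
    n_repeats = sum(spec.repeats for spec in net.stage_specs)
    gap = (count_activation_sites(base, "original")
           - count_activation_sites(base, "modified2"))
    assert gap == n_repeats


# ---------------------------------------------------------------------------
# elementwise activation op
# ---------------------------------------------------------------------------

def test_activation_definitions():
    assert models.activation("silu", 0.0) == 0.0
    assert models.activation("relu", -3.7) == 0.0
    assert models.activation("relu", 2.0) == 2.0
    assert models.activation("silu", 1.0) == pytest.approx(
        1.0 / (1.0 + math.exp(-1.0)), rel=1e-12)  # 0.731058...
    with pytest.raises(ValueError):
        models.activation("gelu", 1.0)


# ---------------------------------------------------------------------------
# SE forward semantics
# ---------------------------------------------------------------------------

def test_se_zero_map_stays_zero(rng):
    se = SEConfig(present=True)
    w = {"w1": rng.normal(size=(1, 2)), "b1": rng.normal(size=1),
         "w2": rng.normal(size=(2, 1)), "b2": rng.normal(size=2)}
    out = se_forward(np.zeros((2, 4, 4), dtype=np.float32), se, w)
    assert np.all(out == 0.0)


def test_dummy_se_is_bitwise_identity(rng):
    x = rng.normal(size=(3, 5, 5)).astype(np.float32)
    out = se_forward(x, SEConfig(present=False))
    assert out is x or np.array_equal(out, x)


def test_se_two_channel_hand_computation():
    """C=2, H=W=1: gates recomputed by hand through GAP-FC-SiLU-FC-sigmoid."""
    x = np.array([[[2.0]], [[-1.0]]], dtype=np.float32)  # (2,1,1)
    w1 = np.array([[0.5, -0.25]])  # squeeze to width 1
    b1 = np.array([0.1])
    w2 = np.array([[1.5], [-2.0]])
    b2 = np.array([0.2, -0.3])
    z1 = 0.5 * 2.0 + (-0.25) * (-1.0) + 0.1  # GAP == identity at 1x1
    a1 = z1 / (1.0 + math.exp(-z1))
    gates = [1.0 / (1.0 + math.exp(-(1.5 * a1 + 0.2))),
             1.0 / (1.0 + math.exp(-(-2.0 * a1 - 0.3)))]
    out = se_forward(x, SEConfig(present=True),
                     {"w1": w1, "b1": b1, "w2": w2, "b2": b2})
    assert out[0, 0, 0] == pytest.approx(2.0 * gates[0], rel=1e-5)
    assert out[1, 0, 0] == pytest.approx(-1.0 * gates[1], rel=1e-5)


def test_se_channel_mismatch_rejected(rng):
    w = {"w1": rng.normal(size=(1, 4)), "b1": np.zeros(1),
         "w2": rng.normal(size=(4, 1)), "b2": np.zeros(4)}
    with pytest.raises(ValueError, match="channel mismatch"):
        se_forward(np.zeros((2, 3, 3), dtype=np.float32), SEConfig(True), w)


def test_se_saturation_limit_matches_dummy(rng):
    """Gates forced to 1 make an SE block behave like its SE-free twin."""
    blk = models.MBConv(8, 8, 3, 1, 6, VariantConfig.from_name("original"),
                        SEConfig(), np.random.default_rng(5))
    x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
    blk.se.w2.data[...] = 0.0
    blk.se.b2.data[...] = 30.0  # sigmoid(30) ~ 1
    out_sat = blk.forward(x)
    se_backup = blk.se
    blk.se = nn.DummySE()
    out_dummy = blk.forward(x)
    blk.se = se_backup
    assert np.allclose(out_sat, out_dummy, rtol=1e-4, atol=1e-5)


# ---------------------------------------------------------------------------
# build contracts
# ---------------------------------------------------------------------------

def test_unknown_base_and_bad_classes_rejected():
    with pytest.raises(ValueError, match="unknown base"):
        build_model("B9", "original")
    with pytest.raises(ValueError, match="num_classes"):
        build_model("B0", "original", num_classes=1)
    with pytest.raises(ValueError, match="unknown variant"):
        build_model("B0", "modified9")


def test_variant_table_matches_configuration():
    assert VariantConfig.from_name("original") == VariantConfig("original", "silu", True)
    assert VariantConfig.from_name("modified1") == VariantConfig("modified1", "relu", True)
    assert VariantConfig.from_name("modified2") == VariantConfig("modified2", "silu", False)
    assert VariantConfig.from_name("Modified 3") == VariantConfig("modified3", "relu", False)


@pytest.mark.parametrize("variant", models.VARIANTS)
def test_forward_shape_contract(variant, rng):
    net = build_model("B0", variant, num_classes=2, seed=0)
    x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
    out = net.forward(x)
    assert out.shape == (2, 2)
    emb = net.features(x)
    assert emb.shape == (2, net.embedding_dim)


def test_b0_embedding_dim_is_1280(b0_original):
    assert b0_original.embedding_dim == 1280


def test_same_seed_identical_weights():
    a = build_model("B0", "modified3", 2, seed=11)
    b = build_model("B0", "modified3", 2, seed=11)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        assert np.array_equal(pa.data, pb.data)


def test_checkpoint_roundtrip(tmp_path, rng):
    net = build_model("B0", "modified3", 2, seed=3)
    x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
    before = net.forward(x)
    models.save_checkpoint(net, tmp_path / "ckpt.npz")
    loaded = models.load_checkpoint(tmp_path / "ckpt.npz")
    assert np.allclose(loaded.forward(x), before)
    meta_path = tmp_path / "ckpt.npz.json"
    assert meta_path.exists()


def test_scaling_invariants():
    assert SCALINGS["B0"].width_mult == 1.0 and SCALINGS["B0"].depth_mult == 1.0
    for cfg in SCALINGS.values():
        assert cfg.input_resolution == 224
    with pytest.raises(ValueError):
        models.ScalingConfig("bad", 0.5, 1.0)
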