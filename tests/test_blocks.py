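"""Unit and property tests for the shuffle / grouped-conv / CoT primitives
and the residual blocks built from them."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cotresnet.autodiff import Tensor
from cotresnet.blocks import (
    BasicCoTBlock,
    BlockSpec,
    CCSBottleneck,
    CoT,
    CoTConfig,
    PlainBasicBlock,
    PlainBottleneck,
    ShuffleBottleneck,
    build_block,
    channel_shuffle,
    shuffle_permutation,
)
from cotresnet.nn import Conv2d

RNG = np.random.default_rng(0)


def labeled_map(c: int, n: int = 2, h: int = 3, w: int = 3) -> np.ndarray:
    """Feature map whose values encode their own channel index."""
    return np.broadcast_to(np.arange(c, dtype=np.float32)[:, None, None], (n, c, h, w)).copy()


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------

def test_shuffle_matches_reshape_transpose_oracle_exhaustively():
    """shuffle == view-(g, C/g)-transpose-flatten for every g | C, C <= 64."""
    for c in range(1, 65):
        for g in range(1, c + 1):
            if c % g:
                continue
            oracle = np.arange(c).reshape(g, c // g).T.reshape(-1)
            shuffled = channel_shuffle(labeled_map(c), g)
            np.testing.assert_array_equal(shuffled[0, :, 0, 0], oracle)
            np.testing.assert_array_equal(shuffle_permutation(c, g), oracle)


def test_shuffle_worked_example_and_identity():
    out = channel_shuffle(labeled_map(6), 2)
    np.testing.assert_array_equal(out[0, :, 0, 0], [0, 3, 1, 4, 2, 5])
    x = RNG.normal(size=(2, 5, 3, 3)).astype(np.float32)
    np.testing.assert_array_equal(channel_shuffle(x, 1), x)


def test_shuffle_composition_inverts():
    """shuffle(g) followed by shuffle(C/g) restores the original order."""
    for c, g in [(6, 2), (6, 3), (64, 4), (12, 6)]:
        x = RNG.normal(size=(1, c, 2, 2)).astype(np.float32)
        np.testing.assert_array_equal(channel_shuffle(channel_shuffle(x, g), c // g), x)


def test_shuffle_divisibility_error_names_counts():
    with pytest.raises(ValueError, match="C=6.*g=4"):
        channel_shuffle(labeled_map(6), 4)


@given(
    c_over_g=st.integers(1, 8),
    g=st.integers(1, 8),
    n=st.integers(1, 3),
    seed=st.integers(0, 2**31 - 1),
)
def test_shuffle_is_bijection_preserving_values(c_over_g, g, n, seed):
    c = c_over_g * g
    x = np.random.default_rng(seed).normal(size=(n, c, 2, 2)).astype(np.float32)
    out = channel_shuffle(x, g)
    assert out.shape == x.shape
    # values preserved as a multiset at every (n, h, w) position
    np.testing.assert_allclose(np.sort(out, axis=1), np.sort(x, axis=1))
    # and it is exactly a permutation of channel indices
    np.testing.assert_array_equal(out, x[:, shuffle_permutation(c, g)])


def test_shuffle_commutes_with_batch_permutation():
    x = RNG.normal(size=(5, 8, 3, 3)).astype(np.float32)
    perm = RNG.permutation(5)
    np.testing.assert_array_equal(
        channel_shuffle(x, 4)[perm], channel_shuffle(x[perm], 4)
    )


def test_shuffle_differentiable_path_matches_array_path():
    x = RNG.normal(size=(2, 8, 3, 3)).astype(np.float32)
    t = Tensor(x, requires_grad=True)
    out = channel_shuffle(t, 2)
    np.testing.assert_array_equal(out.data, channel_shuffle(x, 2))
    out.sum().backward()
    np.testing.assert_array_equal(t.grad, np.ones_like(x))


# ---------------------------------------------------------------------------
# grouped pointwise convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "c_in,c_out,g,expected",
    [
        (256, 64, 4, 4096),  # sum over groups of (C/g)*(out/g) kernels
        (256, 64, 1, 16384),  # g=1 degenerates to plain pointwise
        (8, 16, 2, 64),
        (12, 12, 3, 48),
    ],
)
def test_grouped_pointwise_weight_count(c_in, c_out, g, expected):
    conv = Conv2d(c_in, c_out, 1, groups=g, rng=np.random.default_rng(0))
    assert conv.weight_count() == expected == c_in * c_out // g


def test_grouped_conv_divisibility_error():
    with pytest.raises(ValueError, match="6"):
        Conv2d(6, 8, 1, groups=4)


def test_grouped_conv_groups_are_independent():
    """Output channels of group i depend only on input channels of group i."""
    g, c = 4, 16
    conv = Conv2d(c, c, 1, groups=g, rng=np.random.default_rng(3))
    x = RNG.normal(size=(2, c, 4, 4)).astype(np.float32)
    base = conv(Tensor(x)).data
    x2 = x.copy()
    x2[:, : c // g] += 10.0  # perturb only group 0's inputs
    out2 = conv(Tensor(x2)).data
    assert not np.allclose(out2[:, : c // g], base[:, : c // g])
    np.testing.assert_array_equal(out2[:, c // g :], base[:, c // g :])


def test_grouped_conv_spatial_dims_and_batch_permutation():
    conv = Conv2d(8, 8, 1, groups=2, rng=np.random.default_rng(1))
    x = RNG.normal(size=(4, 8, 5, 7)).astype(np.float32)
    out = conv(Tensor(x)).data
    assert out.shape == (4, 8, 5, 7)
    perm = RNG.permutation(4)
    np.testing.assert_allclose(conv(Tensor(x[perm])).data, out[perm], rtol=1e-5)


# ---------------------------------------------------------------------------
# CoT block
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "shape,k",
    [
        ((2, 64, 56, 56), 3),  # canonical stage-2 size
        ((1, 8, 7, 7), 3),  # minimal legal instance
        ((1, 8, 10, 6), 5),
        ((2, 16, 9, 9), 1),
    ],
)
def test_cot_output_shape_equals_input_shape(shape, k):
    cot = CoT(shape[1], CoTConfig(kernel=k), rng=np.random.default_rng(0))
    out = cot(Tensor(RNG.normal(size=shape).astype(np.float32)))
    assert out.shape == shape
    assert np.isfinite(out.data).all()


def test_cot_attention_weights_sum_to_one_per_position():
    for c, hw, k, heads in [(8, 7, 3, 1), (16, 5, 5, 2), (12, 6, 3, 4)]:
        cot = CoT(c, CoTConfig(kernel=k, heads=heads), rng=np.random.default_rng(1))
        x = Tensor(RNG.normal(size=(2, c, hw, hw)).astype(np.float32))
        w = cot.attention_weights(x).data
        assert w.shape == (2, heads, k * k, hw, hw)
        np.testing.assert_allclose(w.sum(axis=2), 1.0, atol=1e-5)


def test_cot_zero_value_branch_reduces_to_static_context():
    """With the value embedding zeroed, the dynamic branch vanishes: Y = K1."""
    cot = CoT(8, rng=np.random.default_rng(2))
    cot.value_embed[0].weight.data[:] = 0.0
    x = Tensor(RNG.normal(size=(2, 8, 6, 6)).astype(np.float32))
    np.testing.assert_array_equal(cot(x).data, cot.key_embed(x).data)


def test_cot_channel_mismatch_raises():
    cot = CoT(8, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="C=8"):
        cot(Tensor(np.zeros((1, 4, 5, 5), dtype=np.float32)))


def test_cot_config_validation():
    with pytest.raises(ValueError):
        CoTConfig(kernel=4)
    with pytest.raises(ValueError, match="heads"):
        CoT(6, CoTConfig(heads=4))


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------

def _spec(kind, in_ch, mid, stride=1, groups=1):
    cot = CoTConfig() if kind in ("basic_cot", "ccs_bottleneck") else None
    return BlockSpec(kind=kind, in_channels=in_ch, mid_channels=mid,
                     stride=stride, groups=groups, cot=cot)


ALL_KINDS = [
    ("basic_cot", 1),
    ("plain_basic", 1),
    ("ccs_bottleneck", 4),
    ("plain_bottleneck", 1),
    ("bottleneck_shuffle_only", 4),
]


@pytest.mark.parametrize("kind,groups", ALL_KINDS)
def test_block_forward_shapes_stride1_and_stride2(kind, groups):
    rng = np.random.default_rng(5)
    x = Tensor(RNG.normal(size=(2, 8, 12, 12)).astype(np.float32))

    b1 = build_block(_spec(kind, 8, 8, stride=1, groups=groups), rng=rng)
    out1 = b1(x)
    assert out1.shape == (2, b1.spec.out_channels, 12, 12)

    b2 = build_block(_spec(kind, 8, 16, stride=2, groups=groups), rng=rng)
    out2 = b2(x)
    assert out2.shape == (2, b2.spec.out_channels, 6, 6)
    assert np.isfinite(out2.data).all()


def test_basic_cot_block_canonical_stage_shapes():
    rng = np.random.default_rng(6)
    x = Tensor(RNG.normal(size=(1, 64, 56, 56)).astype(np.float32))
    same = BasicCoTBlock(_spec("basic_cot", 64, 64, stride=1), rng=rng)
    assert same(x).shape == (1, 64, 56, 56)
    down = BasicCoTBlock(_spec("basic_cot", 64, 128, stride=2), rng=rng)
    assert down(x).shape == (1, 128, 28, 28)


def test_ccs_bottleneck_expands_channels_4x():
    rng = np.random.default_rng(7)
    x = Tensor(RNG.normal(size=(1, 64, 14, 14)).astype(np.float32))
    block = CCSBottleneck(_spec("ccs_bottleneck", 64, 64, groups=4), rng=rng)
    assert block(x).shape == (1, 256, 14, 14)


def _param_count(module):
    return sum(p.data.size for p in module.parameters())


def test_ccs_bottleneck_fewer_params_than_plain_and_g1_collapse():
    rng = np.random.default_rng(8)
    ccs = CCSBottleneck(_spec("ccs_bottleneck", 64, 64, groups=4), rng=rng)
    plain = PlainBottleneck(_spec("plain_bottleneck", 64, 64), rng=rng)
    assert _param_count(ccs) < _param_count(plain)
    # degenerate configuration: g=1 and a 3×3 conv core == plain bottleneck
    collapsed = ShuffleBottleneck(_spec("bottleneck_shuffle_only", 64, 64, groups=1), rng=rng)
    assert _param_count(collapsed) == _param_count(plain)


def test_ccs_bottleneck_divisibility_error():
    with pytest.raises(ValueError, match="groups"):
        _spec("ccs_bottleneck", 64, 6, groups=4)


def test_block_stride_validation():
    with pytest.raises(ValueError, match="stride"):
        _spec("plain_basic", 8, 8, stride=3)


@pytest.mark.parametrize("kind,groups", ALL_KINDS)
def test_zeroed_residual_branch_gives_activated_shortcut(kind, groups):
    """Residual contract: with the branch's final norm zeroed, the block is
    an activated (projected) identity."""
    rng = np.random.default_rng(9)
    block = build_block(_spec(kind, 8, 16, stride=2, groups=groups), rng=rng)
    final_bn = block.bn2 if kind in ("basic_cot", "plain_basic") else block.bn3
    final_bn.gamma.data[:] = 0.0
    final_bn.beta.data[:] = 0.0
    x = Tensor(RNG.normal(size=(2, 8, 8, 8)).astype(np.float32))
    np.testing.assert_allclose(
        block(x).data, block.shortcut(x).relu().data, rtol=1e-5, atol=1e-6
    )


@pytest.mark.parametrize("kind,groups", ALL_KINDS)
def test_gradient_flows_through_every_block_variant(kind, groups):
    rng = np.random.default_rng(10)
    block = build_block(_spec(kind, 8, 8, stride=1, groups=groups), rng=rng)
    x = Tensor(RNG.normal(size=(2, 8, 6, 6)).astype(np.float32))
    (block(x) ** 2).sum().backward()
    for name, p in block.named_parameters():
        assert p.grad is not None, f"{kind}: no gradient for {name}"
        assert np.isfinite(p.grad).all(), f"{kind}: non-finite gradient for {name}"
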