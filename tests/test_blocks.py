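"""Tests of the bespoke operators: the receptive-field formula, the
large-kernel attention block, the multi-scale group block, the spatial
shift / shift-pointwise operator and the Aggregating-Shift decoder stage.

The two key equivalence oracles are built independently of the layer
implementations: the depthwise cascade is compared against an explicitly
composed dense kernel, and the shift-pointwise operator against a sparse
3x3 convolution assembled tap by tap.
"""

import numpy as np
import pytest
from scipy import signal

from lkmu import DLKA, MSGP, SHIFT_DISPLACEMENTS, SPPW, receptive_field, spatial_shift
from lkmu.blocks import AggShiftDecoder
from lkmu.nn import autograd as ag


# ---------------------------------------------------------------------------
# receptive field formula
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k1,k2,r,expected", [
    (3, 7, 5, 33),   # default large-kernel decomposition
    (3, 3, 5, 13),   # ablation setting A
    (3, 5, 5, 23),   # ablation setting B
    (3, 9, 5, 43),   # ablation setting D
    (1, 1, 5, 1),    # degenerate 1x1 cascade
])
def test_receptive_field_values(k1, k2, r, expected):
    assert receptive_field(k1, k2, r) == expected


def test_receptive_field_monotonicity():
    # strictly increasing in k2, and in r for k2 > 1
    values_k2 = [receptive_field(3, k2, 5) for k2 in (3, 5, 7, 9, 11)]
    assert all(b > a for a, b in zip(values_k2, values_k2[1:]))
    values_r = [receptive_field(3, 7, r) for r in range(1, 8)]
    assert all(b > a for a, b in zip(values_r, values_r[1:]))
    # for k2 == 1 the rate has no effect
    assert receptive_field(3, 1, 1) == receptive_field(3, 1, 9)


@pytest.mark.parametrize("bad", [(2, 7, 5), (3, 4, 5), (0, 3, 5), (-3, 3, 5),
                                 (3, 3, 0)])
def test_receptive_field_rejects_invalid(bad):
    with pytest.raises(ValueError):
        receptive_field(*bad)


# ---------------------------------------------------------------------------
# DLKA
# ---------------------------------------------------------------------------

def test_dlka_shape_contract(rng):
    block = DLKA(32, 64, rng=rng)
    x = ag.Tensor(rng.standard_normal((1, 32, 16, 16)).astype(np.float32))
    assert block(x).data.shape == (1, 64, 16, 16)
    with pytest.raises(ValueError, match="channels"):
        block(ag.Tensor(np.zeros((1, 16, 16, 16), np.float32)))


def test_dlka_zero_gated_attention_is_identity(rng):
    """With the attention batch-norm scale and shift forced to zero the
    attention map vanishes, and since the output pointwise conv is
    bias-free, the block reduces to the identity on the expanded input."""
    block = DLKA(8, 8, rng=rng)
    block.eval()
    block.bn_att.weight.data[:] = 0.0
    block.bn_att.bias.data[:] = 0.0
    x = ag.Tensor(rng.standard_normal((2, 8, 12, 12)).astype(np.float32))
    out = block(x).data
    x1 = block.act(block.bn_in(block.pw_in(x))).data
    np.testing.assert_allclose(out, x1, atol=1e-6)


def compose_depthwise_kernels(k_small, k_dilated, rate):
    """Dense per-channel kernel equivalent to DW(k_small) then
    DWD(k_dilated, rate): the convolution of the first kernel with the
    zero-upsampled second kernel."""
    C, _, k1, _ = k_small.shape
    k2 = k_dilated.shape[2]
    size = rate * (k2 - 1) + 1
    dense = np.zeros((C, 1, k1 + size - 1, k1 + size - 1))
    for c in range(C):
        up = np.zeros((size, size))
        up[::rate, ::rate] = k_dilated[c, 0]
        dense[c, 0] = signal.convolve2d(k_small[c, 0], up, mode="full")
    return dense.astype(np.float32)


@pytest.mark.parametrize("k2", [3, 5, 7, 9])
def test_depthwise_cascade_equals_composed_dense_kernel(rng, k2):
    """DW3 followed by DWD(k2, rate 5) equals a single dense depthwise
    convolution with the composed kernel; compared on the interior region
    where the cascade's intermediate zero padding is not visible."""
    C, rate = 4, 5
    rf = receptive_field(3, k2, rate)
    pad = (rf - 1) // 2
    H = rf + 31  # interior at least 32 wide... actually 32x32 after crop
    x = rng.standard_normal((1, C, H, H)).astype(np.float32)
    w1 = rng.standard_normal((C, 1, 3, 3)).astype(np.float32)
    w2 = rng.standard_normal((C, 1, k2, k2)).astype(np.float32)

    h = ag.conv2d(ag.Tensor(x), ag.Tensor(w1), groups=C)
    cascade = ag.conv2d(h, ag.Tensor(w2), dilation=rate, groups=C).data

    dense = compose_depthwise_kernels(w1, w2, rate)
    assert dense.shape[2] == rf  # the receptive-field formula in kernel form
    single = ag.conv2d(ag.Tensor(x), ag.Tensor(dense), groups=C).data

    interior = (slice(None), slice(None), slice(pad, -pad), slice(pad, -pad))
    np.testing.assert_allclose(cascade[interior], single[interior],
                               atol=1e-4 * np.abs(single[interior]).max())


# ---------------------------------------------------------------------------
# MSGP
# ---------------------------------------------------------------------------

def test_msgp_preserves_shape_and_split(rng):
    block = MSGP(64, rng=rng)
    x = ag.Tensor(rng.standard_normal((1, 64, 16, 16)).astype(np.float32))
    assert block(x).data.shape == (1, 64, 16, 16)
    with pytest.raises(ValueError, match="divisible by 4"):
        MSGP(30, rng=rng)
    with pytest.raises(ValueError, match="increasing"):
        MSGP(64, rates=(7, 3, 11), rng=rng)


def test_msgp_zeroed_convs_keep_identity_path(rng):
    """With every dilated conv weight and BN shift zeroed the three
    processed paths vanish; the output is Concat(f1, 0, 0, 0) + input."""
    block = MSGP(16, rng=rng)
    block.eval()
    for conv in block.convs:
        conv.weight.data[:] = 0.0
    for bn in block.bns:
        bn.bias.data[:] = 0.0
    x = rng.standard_normal((2, 16, 8, 8)).astype(np.float32)
    out = block(ag.Tensor(x)).data
    expected = x.copy()
    expected[:, :4] += x[:, :4]
    np.testing.assert_allclose(out, expected, atol=1e-6)


@pytest.mark.parametrize("adder", ["raw", "processed"])
def test_msgp_adder_variants_run_and_differ(rng, adder):
    block = MSGP(16, adder=adder, rng=np.random.default_rng(3))
    x = ag.Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))
    out = block(x)
    assert out.data.shape == x.data.shape
    assert np.isfinite(out.data).all()


# ---------------------------------------------------------------------------
# spatial shift / SPPW
# ---------------------------------------------------------------------------

def test_spatial_shift_displacement_spec():
    d = SHIFT_DISPLACEMENTS
    assert len(d) == 8 and len(set(d)) == 8
    assert all(max(abs(dy), abs(dx)) == 1 for dy, dx in d)


def test_spatial_shift_constant_input_zero_borders():
    """On a constant-1 input each 5x5 channel keeps value 1 except the
    single border row/column vacated by its group's displacement."""
    x = np.ones((1, 8, 5, 5), np.float32)
    y = spatial_shift(x)
    for g, (dy, dx) in enumerate(SHIFT_DISPLACEMENTS):
        expected = np.ones((5, 5), np.float32)
        if dy == 1:
            expected[0, :] = 0
        elif dy == -1:
            expected[-1, :] = 0
        if dx == 1:
            expected[:, 0] = 0
        elif dx == -1:
            expected[:, -1] = 0
        np.testing.assert_array_equal(y[0, g], expected)


def test_spatial_shift_moves_single_pixel():
    for g, (dy, dx) in enumerate(SHIFT_DISPLACEMENTS):
        x = np.zeros((1, 8, 7, 7), np.float32)
        x[0, g, 3, 3] = 1.0
        y = spatial_shift(x)
        assert y[0, g, 3 + dy, 3 + dx] == 1.0
        assert y.sum() == 1.0
        # pixel at the corner vanishes off-grid for diagonal shifts
        x2 = np.zeros((1, 8, 7, 7), np.float32)
        x2[0, g, 0 if dy < 0 else 6, 0 if dx < 0 else 6] = 1.0
        if dy != 0 or dx != 0:
            pass  # all displacements are nonzero by spec
        y2 = spatial_shift(x2)
        assert y2[0, g].sum() == 0.0


def test_spatial_shift_is_linear_and_mass_non_increasing(rng):
    x = rng.standard_normal((2, 16, 9, 9)).astype(np.float32)
    y = rng.standard_normal((2, 16, 9, 9)).astype(np.float32)
    a, b = 1.7, -0.4
    np.testing.assert_allclose(
        spatial_shift(a * x + b * y),
        a * spatial_shift(x) + b * spatial_shift(y), atol=1e-5)
    assert np.abs(spatial_shift(x)).sum() <= np.abs(x).sum() + 1e-6


def sppw_equivalent_conv_kernel(pw_weight, channels):
    """The sparse 3x3 kernel equal to shift-then-pointwise: input channel c
    (group g) contributes only at tap -d_g with the pointwise weight."""
    O = pw_weight.shape[0]
    k = np.zeros((O, channels, 3, 3), np.float32)
    q = channels // 8
    for c in range(channels):
        g = min(c // q, 7)
        if c >= 8 * q:
            dy = dx = 0  # remainder channels are unshifted
        else:
            dy, dx = SHIFT_DISPLACEMENTS[g]
        k[:, c, 1 - dy, 1 - dx] = pw_weight[:, c, 0, 0]
    return k


@pytest.mark.parametrize("channels", [16, 32, 96, 416])
def test_sppw_equals_constrained_3x3_convolution(rng, channels):
    out_channels = max(4, channels // 8)
    x = rng.standard_normal((1, channels, 12, 12)).astype(np.float32)
    pw = rng.standard_normal((out_channels, channels, 1, 1)).astype(np.float32)
    shifted = ag.spatial_shift(ag.Tensor(x))
    got = ag.conv2d(shifted, ag.Tensor(pw)).data
    kernel = sppw_equivalent_conv_kernel(pw, channels)
    want = ag.conv2d(ag.Tensor(x), ag.Tensor(kernel)).data
    np.testing.assert_allclose(got, want, atol=1e-5 * max(1.0, np.abs(want).max()))


def test_sppw_zero_input_gives_bn_shift(rng):
    block = SPPW(16, 8, rng=rng)
    block.eval()
    block.bn.bias.data[:] = rng.standard_normal(8).astype(np.float32)
    x = ag.Tensor(np.zeros((1, 16, 6, 6), np.float32))
    out = block(x).data
    expected = np.maximum(block.bn.bias.data, 0.0)
    np.testing.assert_allclose(out, expected[None, :, None, None]
                               * np.ones_like(out), atol=1e-6)


# ---------------------------------------------------------------------------
# Aggregating-Shift decoder
# ---------------------------------------------------------------------------

def test_aggshift_channel_budget(rng):
    block = AggShiftDecoder(416, 160, rng=rng)
    x = ag.Tensor(rng.standard_normal((1, 416, 8, 8)).astype(np.float32))
    assert block(x).data.shape == (1, 160, 8, 8)
    for c0 in (32, 64, 128, 160):
        assert c0 // 2 + c0 // 4 + c0 // 4 == c0
    with pytest.raises(ValueError, match="divisible by 4"):
        AggShiftDecoder(416, 30, rng=rng)
    with pytest.raises(ValueError, match="variant"):
        AggShiftDecoder(416, 160, variant="bogus", rng=rng)


def test_aggshift_zeroed_tails_reduce_to_aggregation(rng):
    """Zeroing both trailing pointwise convolutions and their BN shifts
    makes the decoder output equal the (already nonnegative) aggregated
    multi-path feature."""
    block = AggShiftDecoder(32, 16, rng=rng)
    block.eval()
    block.tail2.pw.weight.data[:] = 0.0
    block.tail2.bn.bias.data[:] = 0.0
    x = ag.Tensor(rng.standard_normal((1, 32, 8, 8)).astype(np.float32))
    out = block(x).data
    yd = ag.concat([block.path_shift(x), block.path_group(x),
                    block.path_dilated(x)], axis=1).data
    np.testing.assert_allclose(out, yd, atol=1e-6)
    assert (yd >= 0).all()
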