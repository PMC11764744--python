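"""The bespoke operators of LKMU-Lite.

* :class:`DLKA` — decoupled large-kernel attention: a pointwise expansion,
  a depthwise 3x3 + depthwise-dilated KxK (rate r) cascade that emulates a
  single large kernel, a pointwise channel mixer producing the attention
  map, and Hadamard gating with a residual connection.
* :class:`MSGP` — multi-scale group perception: a 4-way channel split with
  one identity path and three 3x3 dilated convolutions (rates 3/7/11) wired
  with adders between adjacent paths, concatenated back and added to the
  input.
* :class:`SPPW` — the parameter-free 8-direction spatial shift followed by
  a pointwise convolution, equivalent in receptive field to a (sparse)
  3x3 convolution.
* :class:`AggShiftDecoder` — the lightweight decoder stage: a three-path
  aggregation (SPPW to C0/2, grouped 3x3 to C0/4, dilated 3x3 to C0/4)
  followed by two trailing SPPW operators and a residual connection.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import autograd as ag

__all__ = [
    "receptive_field",
    "DLKA",
    "MSGP",
    "SPPW",
    "AggShiftDecoder",
    "Conv3x3Decoder",
    "spatial_shift",
    "SHIFT_DISPLACEMENTS",
]

SHIFT_DISPLACEMENTS = ag.SHIFT_DISPLACEMENTS


def receptive_field(k1: int, k2: int, r: int) -> int:
    """Equivalent receptive-field side of a depthwise k1 convolution
    cascaded with a depthwise-dilated k2 convolution at rate ``r``:

        R = k1 + k2 + (k2 - 1) * (r - 1) - 1
    """
    for k in (k1, k2):
        if not isinstance(k, (int, np.integer)) or k < 1 or k % 2 == 0:
            raise ValueError(f"kernel sizes must be positive odd integers, got {k}")
    if not isinstance(r, (int, np.integer)) or r < 1:
        raise ValueError(f"dilation rate must be a positive integer, got {r}")
    return int(k1 + k2 + (k2 - 1) * (r - 1) - 1)


def spatial_shift(x: np.ndarray, displacements=SHIFT_DISPLACEMENTS) -> np.ndarray:
    """Parameter-free group-wise spatial shift on a plain NCHW array."""
    x = np.asarray(x, dtype=np.float32)
    return ag.spatial_shift(ag.Tensor(x), displacements).data


class DLKA(nn.Module):
    """Decoupled Large Kernel Attention.

    The stage's channel change happens exclusively in the first pointwise
    convolution; every other operator preserves the channel count.
    """

    def __init__(self, in_channels, out_channels, dw_kernel=3, dwd_kernel=7,
                 dilation=5, rng=None):
        super().__init__()
        if out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.rf = receptive_field(dw_kernel, dwd_kernel, dilation)
        self.pw_in = nn.Conv2d(in_channels, out_channels, 1, rng=rng)
        self.bn_in = nn.BatchNorm2d(out_channels)
        self.act = nn.ReLU()
        self.dw = nn.Conv2d(out_channels, out_channels, dw_kernel,
                            groups=out_channels, rng=rng)
        self.dwd = nn.Conv2d(out_channels, out_channels, dwd_kernel,
                             dilation=dilation, groups=out_channels, rng=rng)
        self.pw_att = nn.Conv2d(out_channels, out_channels, 1, rng=rng)
        self.bn_att = nn.BatchNorm2d(out_channels)
        self.pw_out = nn.Conv2d(out_channels, out_channels, 1, rng=rng)

    def forward(self, x):
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"DLKA expects {self.in_channels} input channels, "
                f"got {x.data.shape[1]}")
        x1 = self.act(self.bn_in(self.pw_in(x)))
        att = self.bn_att(self.pw_att(self.dwd(self.dw(x1))))
        return self.pw_out(ag.mul(att, x1)) + x1


class MSGP(nn.Module):
    """Multi-scale Group Perception.

    ``adder`` selects the operand of the adjacent-path adders: ``"raw"``
    adds the raw split of the neighbouring path (the default), while
    ``"processed"`` adds the already-convolved neighbouring output
    (Res2Net convention).  Parameter count is identical either way.
    """

    def __init__(self, channels, rates=(3, 7, 11), adder="raw", rng=None):
        super().__init__()
        if channels % 4:
            raise ValueError("MSGP channels must be divisible by 4")
        if not (rates[0] < rates[1] < rates[2]):
            raise ValueError("dilation rates must be strictly increasing")
        if adder not in ("raw", "processed"):
            raise ValueError("adder must be 'raw' or 'processed'")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.rates = tuple(rates)
        self.adder = adder
        q = channels // 4
        self.convs = nn.ModuleList([
            nn.Conv2d(q, q, 3, dilation=r, rng=rng) for r in rates
        ])
        self.bns = nn.ModuleList([nn.BatchNorm2d(q) for _ in rates])
        self.act = nn.ReLU()

    def forward(self, x):
        if x.data.shape[1] != self.channels:
            raise ValueError(
                f"MSGP expects {self.channels} channels, got {x.data.shape[1]}")
        q = self.channels // 4
        parts = [ag.narrow(x, 1, i * q, q) for i in range(4)]
        outs = [parts[0]]
        for i in range(1, 4):
            neighbour = parts[i - 1] if self.adder == "raw" else outs[i - 1]
            h = self.convs[i - 1](parts[i] + neighbour)
            outs.append(self.act(self.bns[i - 1](h)))
        return ag.concat(outs, axis=1) + x


class SPPW(nn.Module):
    """Spatial shift followed by pointwise convolution (+BN, optional ReLU)."""

    def __init__(self, in_channels, out_channels, relu=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.pw = nn.Conv2d(in_channels, out_channels, 1, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)
        self.act = nn.ReLU() if relu else None

    def forward(self, x):
        y = self.bn(self.pw(ag.spatial_shift(x)))
        return self.act(y) if self.act is not None else y


class _Conv3x3BN(nn.Module):
    """Plain 3x3 conv + BN (+ optional ReLU); the SPPW replacement used by
    the ``conv3x3_mod`` decoder ablation."""

    def __init__(self, in_channels, out_channels, relu=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv = nn.Conv2d(in_channels, out_channels, 3, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)
        self.act = nn.ReLU() if relu else None

    def forward(self, x):
        y = self.bn(self.conv(x))
        return self.act(y) if self.act is not None else y


def _mix_op(variant, in_channels, out_channels, relu, rng):
    if variant == "aggshift":
        return SPPW(in_channels, out_channels, relu=relu, rng=rng)
    return _Conv3x3BN(in_channels, out_channels, relu=relu, rng=rng)


class AggShiftDecoder(nn.Module):
    """Aggregating-Shift decoder stage.

    Three aggregation paths split the C0 output budget as C0/2 + C0/4 +
    C0/4, followed by two trailing shift-pointwise operators and a
    residual connection (the second trailing operator is BN-only before
    the addition; ReLU is applied after).

    ``variant="conv3x3_mod"`` swaps every shift-pointwise operator for a
    plain 3x3 convolution with the same channel budget.  ``trailing``
    exists for ablation: setting it False removes the two trailing
    operators (the residual then wraps the identity).
    """

    def __init__(self, in_channels, out_channels, variant="aggshift",
                 trailing=True, rng=None):
        super().__init__()
        if out_channels % 4:
            raise ValueError("decoder output channels must be divisible by 4")
        if variant not in ("aggshift", "conv3x3_mod"):
            raise ValueError(f"unknown decoder variant {variant!r}")
        rng = rng or np.random.default_rng(0)
        c0 = out_channels
        self.out_channels = c0
        self.path_shift = _mix_op(variant, in_channels, c0 // 2, True, rng)
        self.path_group = nn.Sequential(
            nn.Conv2d(in_channels, c0 // 4, 3, groups=4, rng=rng),
            nn.BatchNorm2d(c0 // 4),
            nn.ReLU(),
        )
        self.path_dilated = nn.Sequential(
            nn.Conv2d(in_channels, c0 // 4, 3, dilation=3, rng=rng),
            nn.BatchNorm2d(c0 // 4),
            nn.ReLU(),
        )
        if trailing:
            self.tail1 = _mix_op(variant, c0, c0, True, rng)
            self.tail2 = _mix_op(variant, c0, c0, False, rng)
        else:
            self.tail1 = None
            self.tail2 = None
        self.act = nn.ReLU()

    def forward(self, x):
        yd = ag.concat(
            [self.path_shift(x), self.path_group(x), self.path_dilated(x)],
            axis=1)
        if self.tail1 is None:
            return self.act(yd)
        return self.act(self.tail2(self.tail1(yd)) + yd)


class Conv3x3Decoder(nn.Module):
    """All-3x3 decoder stage (ablation baseline): two sequential
    3x3 conv + BN + ReLU blocks with a pointwise-projected residual.
    The composition of the published baseline is under-specified; this
    stage is provided for completeness, not verified against printed
    complexity figures."""

    def __init__(self, in_channels, out_channels, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.out_channels = out_channels
        self.body = nn.Sequential(
            nn.Conv2d(in_channels, out_channels, 3, rng=rng),
            nn.BatchNorm2d(out_channels),
            nn.ReLU(),
            nn.Conv2d(out_channels, out_channels, 3, rng=rng),
            nn.BatchNorm2d(out_channels),
            nn.ReLU(),
        )
        self.proj = nn.Sequential(
            nn.Conv2d(in_channels, out_channels, 1, rng=rng),
            nn.BatchNorm2d(out_channels),
        )

    def forward(self, x):
        return self.body(x) + self.proj(x)
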