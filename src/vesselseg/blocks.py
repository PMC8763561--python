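"""Building blocks of the multiscale attention U-Net.

All blocks are tensor-to-tensor modules over the in-package autodiff
engine (layout NCHW) and preserve spatial dimensions:

* :class:`GCNBlock` — large-kernel convolution factorised into two
  summed branches (1xk then kx1, and kx1 then 1xk); per branch this
  costs 2/k of the weights of a full kxk convolution.
* :class:`BoundaryRefine` — residual sharpening S* = S + R(S) where R is
  one kxk convolution with ReLU.
* :class:`PositionAttention` / :class:`ChannelAttention` — convolution-
  free self-attention: the affinity matrix is formed directly from
  reshapes of the input (pixel-by-pixel affinity of size (H*W)^2 for PA,
  channel-by-channel of size C^2 for CA), row-softmax normalised, applied
  back to the input and fused by addition followed by batch norm.
* :class:`DenseASPP` — a cascade of 3x3 dilated convolutions where the
  i-th layer sees the concatenation of the branch input and all previous
  outputs (dense connectivity), each emitting ``growth`` channels.
* :class:`MDASPP` — two-resolution DenseASPP: a full-resolution branch
  with dilation rates (6, 7, 8) and a half-resolution branch (average
  pooled) with rates (2, 3, 4), upsampled back, concatenated and fused
  by a 1x1 convolution + batch norm + dropout.
* :class:`ConvLSTMFusion` — the skip and the upsampled decoder map are
  fed as a length-2 sequence through one convolutional LSTM cell (3x3
  gates, zero initial state); the final hidden state is the fused map.
* :class:`SepDilatedConv` — depthwise 3x3 dilated convolution followed
  by a pointwise 1x1 mix.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F

__all__ = [
    "GCNBlock",
    "BoundaryRefine",
    "PositionAttention",
    "ChannelAttention",
    "DenseASPP",
    "MDASPP",
    "ConvLSTMFusion",
    "ConvLSTMCell",
    "SepDilatedConv",
]


class GCNBlock(nn.Module):
    """Factorised large-kernel convolution: (1xk -> kx1) + (kx1 -> 1xk)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, bias: bool = True,
                 rng=None):
        super().__init__()
        if k % 2 == 0 or k < 3:
            raise ValueError("k must be odd and >= 3")
        self.conv_a1 = nn.Conv2d(in_ch, out_ch, (1, k), bias=bias, rng=rng)
        self.conv_a2 = nn.Conv2d(out_ch, out_ch, (k, 1), bias=bias, rng=rng)
        self.conv_b1 = nn.Conv2d(in_ch, out_ch, (k, 1), bias=bias, rng=rng)
        self.conv_b2 = nn.Conv2d(out_ch, out_ch, (1, k), bias=bias, rng=rng)

    def forward(self, x):
        a = self.conv_a2(self.conv_a1(x))
        b = self.conv_b2(self.conv_b1(x))
        return F.relu(a + b)


class BoundaryRefine(nn.Module):
    """Residual boundary sharpening: S* = S + ReLU(conv_kxk(S))."""

    def __init__(self, ch: int, k: int = 3, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(ch, ch, k, rng=rng)

    def forward(self, s):
        return s + F.relu(self.conv(s))


class PositionAttention(nn.Module):
    """Pixel-to-pixel affinity attention without internal convolutions.

    P (N,C,H,W) is reshaped to PB (N, H*W, C); the (H*W)x(H*W) energy
    PS = rowsoftmax(PB @ PB^T) re-weights PB, and the result is added
    back to P and batch-normalised.  Intended for bottleneck-adjacent
    resolutions where (H*W)^2 stays small.
    """

    def __init__(self, ch: int, rng=None):
        super().__init__()
        self.bn = nn.BatchNorm2d(ch)

    def forward(self, p):
        N, C, H, W = p.shape
        pb = p.transpose(0, 2, 3, 1).reshape(N, H * W, C)
        pc = pb.transpose(0, 2, 1)  # (N, C, H*W)
        ps = F.softmax(F.matmul(pb, pc), axis=-1)  # (N, HW, HW) row-stochastic
        pf = F.matmul(ps, pb)  # (N, HW, C)
        pf = pf.reshape(N, H, W, C).transpose(0, 3, 1, 2)
        return self.bn(p + pf)

    @staticmethod
    def energy(p_data: np.ndarray) -> np.ndarray:
        """Row-stochastic position energy of a raw (N,C,H,W) array."""
        N, C, H, W = p_data.shape
        pb = p_data.transpose(0, 2, 3, 1).reshape(N, H * W, C)
        e = pb @ pb.transpose(0, 2, 1)
        e = e - e.max(axis=-1, keepdims=True)
        e = np.exp(e)
        return e / e.sum(axis=-1, keepdims=True)


class ChannelAttention(nn.Module):
    """Channel-to-channel affinity attention without internal convolutions.

    The CxC energy CS = rowsoftmax(CB^T @ CB) is independent of the
    spatial extent; the re-weighted map is added to the input and
    batch-normalised.
    """

    def __init__(self, ch: int, rng=None):
        super().__init__()
        self.bn = nn.BatchNorm2d(ch)

    def forward(self, c):
        N, C, H, W = c.shape
        cb = c.transpose(0, 2, 3, 1).reshape(N, H * W, C)
        cc = cb.transpose(0, 2, 1)  # (N, C, H*W)
        cs = F.softmax(F.matmul(cc, cb), axis=-1)  # (N, C, C) row-stochastic
        cf = F.matmul(cb, cs.transpose(0, 2, 1))  # (N, HW, C)
        cf = cf.reshape(N, H, W, C).transpose(0, 3, 1, 2)
        return self.bn(c + cf)

    @staticmethod
    def energy(c_data: np.ndarray) -> np.ndarray:
        """Row-stochastic channel energy of a raw (N,C,H,W) array."""
        N, C, H, W = c_data.shape
        cb = c_data.transpose(0, 2, 3, 1).reshape(N, H * W, C)
        e = cb.transpose(0, 2, 1) @ cb
        e = e - e.max(axis=-1, keepdims=True)
        e = np.exp(e)
        return e / e.sum(axis=-1, keepdims=True)


class DenseASPP(nn.Module):
    """Densely connected dilated 3x3 convolutions.

    Layer i consumes ``in_ch + i * growth`` channels and emits ``growth``;
    the output is the concatenation of the input with every layer output,
    ``in_ch + len(rates) * growth`` channels wide.
    """

    def __init__(self, in_ch: int, rates: tuple[int, ...], growth: int, rng=None):
        super().__init__()
        if not rates:
            raise ValueError("rates must be non-empty")
        self.rates = tuple(rates)
        self.convs = [
            nn.Conv2d(in_ch + i * growth, growth, 3, dilation=r, rng=rng)
            for i, r in enumerate(self.rates)
        ]

    @property
    def out_ch(self) -> int:
        first = self.convs[0]
        return first.in_ch + len(self.convs) * first.out_ch

    def forward(self, x):
        feats = [x]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else F.concat(feats, axis=1)
            feats.append(F.relu(conv(inp)))
        return F.concat(feats, axis=1)


class MDASPP(nn.Module):
    """Multiscale dense atrous pyramid bottleneck (output dims = input dims).

    High-res branch: 3x3 conv -> DenseASPP rates (6,7,8).
    Low-res branch: 2x2 average pool -> 3x3 conv -> DenseASPP rates
    (2,3,4) -> bilinear resize back to the input grid.
    The branches are concatenated and fused by 1x1 conv -> BN -> ReLU ->
    dropout, returning C channels.
    """

    def __init__(self, ch: int, branch_ch: int | None = None,
                 growth_high: int | None = None, growth_low: int | None = None,
                 rates_high=(6, 7, 8), rates_low=(2, 3, 4),
                 dropout: float = 0.2, rng=None, drop_rng=None):
        super().__init__()
        branch_ch = branch_ch or ch
        growth_high = growth_high or max(ch // 2, 1)
        growth_low = growth_low or max(ch // 2, 1)
        self.conv_high = nn.Conv2d(ch, branch_ch, 3, rng=rng)
        self.conv_low = nn.Conv2d(ch, branch_ch, 3, rng=rng)
        self.aspp_high = DenseASPP(branch_ch, rates_high, growth_high, rng=rng)
        self.aspp_low = DenseASPP(branch_ch, rates_low, growth_low, rng=rng)
        fused = self.aspp_high.out_ch + self.aspp_low.out_ch
        self.fuse = nn.Conv2d(fused, ch, 1, rng=rng)
        self.bn = nn.BatchNorm2d(ch)
        self.drop = nn.Dropout(dropout, rng=drop_rng)

    def forward(self, x):
        H, W = x.shape[-2:]
        hi = self.aspp_high(F.relu(self.conv_high(x)))
        lo = F.avg_pool(x, 2)
        lo = self.aspp_low(F.relu(self.conv_low(lo)))
        lo = F.resize_bilinear(lo, (H, W))
        fused = self.fuse(F.concat([hi, lo], axis=1))
        return self.drop(F.relu(self.bn(fused)))


class ConvLSTMCell(nn.Module):
    """One convolutional LSTM cell: gates are 3x3 convolutions of [x, h]."""

    def __init__(self, ch: int, rng=None):
        super().__init__()
        self.ch = ch
        self.gates = nn.Conv2d(2 * ch, 4 * ch, 3, rng=rng)

    def step(self, x, h, c):
        z = self.gates(F.concat([x, h], axis=1))
        C = self.ch
        i = F.sigmoid(_slice_gate(z, 0, C))
        f = F.sigmoid(_slice_gate(z, 1, C))
        o = F.sigmoid(_slice_gate(z, 2, C))
        g = F.tanh(_slice_gate(z, 3, C))
        c_new = f * c + i * g
        h_new = o * F.tanh(c_new)
        return h_new, c_new

    def forward(self, sequence):
        """Run over a list of (N,C,H,W) tensors from zero initial state."""
        first = sequence[0]
        N, C, H, W = first.shape
        zeros = nn.as_tensor(np.zeros((N, C, H, W), dtype=first.dtype))
        h, c = zeros, zeros
        for x in sequence:
            h, c = self.step(x, h, c)
        return h


def _slice_gate(z, idx: int, ch: int):
    """Channel slice [idx*ch, (idx+1)*ch) of an NCHW tensor."""
    from .nn.tensor import make_op

    lo, hi = idx * ch, (idx + 1) * ch
    out_data = z.data[:, lo:hi]

    def backward(grad):
        if z.requires_grad:
            g = np.zeros_like(z.data)
            g[:, lo:hi] = grad
            z.accumulate_grad(g)

    return make_op(out_data, (z,), backward)


class ConvLSTMFusion(nn.Module):
    """Fuse an encoder skip with the upsampled decoder map.

    The two maps (same dims) form a length-2 temporal sequence — skip
    first, then decoder — through a ConvLSTM with zero initial state;
    the final hidden state is returned.
    """

    def __init__(self, ch: int, rng=None):
        super().__init__()
        self.cell = ConvLSTMCell(ch, rng=rng)

    def forward(self, skip, up):
        if skip.shape != up.shape:
            raise ValueError(f"dim mismatch: skip {skip.shape} vs up {up.shape}")
        return self.cell([skip, up])


class SepDilatedConv(nn.Module):
    """Depthwise 3x3 dilated convolution + pointwise 1x1 mix, with ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rate: int = 1, bias: bool = True,
                 rng=None):
        super().__init__()
        if rate < 1:
            raise ValueError("rate must be >= 1")
        self.depthwise = nn.Conv2d(in_ch, in_ch, 3, dilation=rate,
                                   groups=in_ch, bias=bias, rng=rng)
        self.pointwise = nn.Conv2d(in_ch, out_ch, 1, bias=bias, rng=rng)

    def forward(self, x):
        return F.relu(self.pointwise(self.depthwise(x)))
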