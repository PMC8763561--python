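"""Oracle equivalence and structural invariants of the network blocks.

Each bespoke block is compared on a tiny input against an independent
brute-force computation (explicit loops / matrix algebra on raw numpy
arrays) with the learned weights frozen to known values.
"""

import numpy as np
import pytest

from vesselseg import blocks, nn


RNG = np.random.default_rng(99)


def direct_conv2d(x, w, b=None, dilation=1):
    """Loop-based 'same' cross-correlation oracle; x (C,H,W), w (O,C,kh,kw)."""
    O, C, kh, kw = w.shape
    _, H, W = x.shape
    ph, pw = dilation * (kh - 1) // 2, dilation * (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((O, H, W))
    for o in range(O):
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    out[o] += w[o, c, i, j] * xp[
                        c, i * dilation:i * dilation + H,
                        j * dilation:j * dilation + W]
        if b is not None:
            out[o] += b[o]
    return out


def _freeze(conv, w, b=None):
    conv.weight.data = np.asarray(w, dtype=float)
    if b is not None:
        conv.bias.data = np.asarray(b, dtype=float)


class TestGCN:
    def test_output_shape(self):
        g = blocks.GCNBlock(3, 5, k=3)
        out = g(nn.as_tensor(RNG.normal(size=(2, 3, 6, 7))))
        assert out.shape == (2, 5, 6, 7)

    def test_matches_branch_oracle(self):
        g = blocks.GCNBlock(2, 2, k=3, bias=False)
        x = RNG.normal(size=(1, 2, 4, 4))
        out = g(nn.as_tensor(x)).data[0]
        a = direct_conv2d(direct_conv2d(x[0], g.conv_a1.weight.data),
                          g.conv_a2.weight.data)
        b = direct_conv2d(direct_conv2d(x[0], g.conv_b1.weight.data),
                          g.conv_b2.weight.data)
        np.testing.assert_allclose(out, np.maximum(a + b, 0.0), atol=1e-5)

    @pytest.mark.parametrize("k,c", [(3, 8), (5, 4), (7, 16)])
    def test_parameter_ratio_is_two_over_k(self, k, c):
        # each branch holds 2*k*C^2 weights vs k^2*C^2 for a full kxk conv
        g = blocks.GCNBlock(c, c, k=k, bias=False)
        branch = g.conv_a1.weight.size + g.conv_a2.weight.size
        full = k * k * c * c
        assert branch * k == 2 * full / k * k  # branch == (2/k) * full
        assert branch == 2 * k * c * c

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            blocks.GCNBlock(2, 2, k=4)


class TestBoundaryRefine:
    def test_zero_residual_is_identity(self):
        br = blocks.BoundaryRefine(3)
        br.conv.weight.data[...] = 0.0
        br.conv.bias.data[...] = 0.0
        x = RNG.normal(size=(1, 3, 5, 5))
        np.testing.assert_array_equal(br(nn.as_tensor(x)).data, x)

    def test_matches_direct_convolution_oracle(self):
        br = blocks.BoundaryRefine(2)
        x = RNG.normal(size=(1, 2, 4, 4))
        out = br(nn.as_tensor(x)).data[0]
        r = direct_conv2d(x[0], br.conv.weight.data, br.conv.bias.data)
        np.testing.assert_allclose(out, x[0] + np.maximum(r, 0.0), atol=1e-5)


def _identity_bn(block):
    """Freeze batch-norm to the identity (eval stats 0/1, eps 0)."""
    block.bn.eps = 0.0
    block.eval()
    return block


class TestAttention:
    def test_position_attention_matches_bruteforce(self):
        pa = _identity_bn(blocks.PositionAttention(3))
        x = RNG.normal(size=(1, 3, 2, 2))
        out = pa(nn.as_tensor(x)).data
        pb = x[0].transpose(1, 2, 0).reshape(4, 3)
        e = np.exp(pb @ pb.T)
        ps = e / e.sum(axis=1, keepdims=True)
        pf = (ps @ pb).reshape(2, 2, 3).transpose(2, 0, 1)
        np.testing.assert_allclose(out[0], x[0] + pf, atol=1e-5)

    def test_channel_attention_matches_bruteforce(self):
        ca = _identity_bn(blocks.ChannelAttention(3))
        x = RNG.normal(size=(1, 3, 2, 2))
        out = ca(nn.as_tensor(x)).data
        cb = x[0].transpose(1, 2, 0).reshape(4, 3)
        e = np.exp(cb.T @ cb)
        cs = e / e.sum(axis=1, keepdims=True)
        cf = (cb @ cs.T).reshape(2, 2, 3).transpose(2, 0, 1)
        np.testing.assert_allclose(out[0], x[0] + cf, atol=1e-5)

    def test_energies_are_row_stochastic(self):
        x = RNG.normal(size=(2, 5, 3, 4))
        ps = blocks.PositionAttention.energy(x)
        cs = blocks.ChannelAttention.energy(x)
        assert ps.shape == (2, 12, 12) and cs.shape == (2, 5, 5)
        np.testing.assert_allclose(ps.sum(axis=-1), 1.0, atol=1e-5)
        np.testing.assert_allclose(cs.sum(axis=-1), 1.0, atol=1e-5)

    def test_shapes_preserved(self):
        x = nn.as_tensor(RNG.normal(size=(1, 4, 3, 5)))
        assert blocks.PositionAttention(4)(x).shape == (1, 4, 3, 5)
        assert blocks.ChannelAttention(4)(x).shape == (1, 4, 3, 5)


class TestDenseASPP:
    def test_dense_connectivity_widths(self):
        d = blocks.DenseASPP(8, (6, 7, 8), growth=4)
        assert [c.in_ch for c in d.convs] == [8, 12, 16]
        assert d.out_ch == 20
        x = nn.as_tensor(RNG.normal(size=(1, 8, 6, 6)))
        assert d(x).shape == (1, 20, 6, 6)

    def test_receptive_field_of_cascade(self):
        # stacked 3x3 convs at rates (6,7,8): RF = 1 + 2*(6+7+8) = 43
        rates = (6, 7, 8)
        assert 1 + sum(2 * r for r in rates) == 43

    def test_spatial_dims_preserved_at_any_rate(self):
        for rate in (1, 4, 9):
            d = blocks.DenseASPP(2, (rate,), growth=2)
            assert d(nn.as_tensor(RNG.normal(size=(1, 2, 5, 7)))).shape \
                == (1, 4, 5, 7)


class TestMDASPP:
    def test_shape_contract_even_and_odd(self):
        m = blocks.MDASPP(4, branch_ch=4, growth_high=2, growth_low=2)
        m.eval()
        for dims in [(8, 8), (65, 33)]:
            x = nn.as_tensor(RNG.normal(size=(1, 4, *dims)))
            assert m(x).shape == (1, 4, *dims)

    def test_branches_are_asymmetric(self):
        m = blocks.MDASPP(4, branch_ch=4, growth_high=2, growth_low=2)
        m.eval()
        x = RNG.normal(size=(1, 4, 8, 8))
        out1 = m(nn.as_tensor(x)).data
        # swap the two dilation-rate triples; outputs must change
        m2 = blocks.MDASPP(4, branch_ch=4, growth_high=2, growth_low=2,
                           rates_high=(2, 3, 4), rates_low=(6, 7, 8))
        m2.load_state_dict(m.state_dict())
        m2.eval()
        out2 = m2(nn.as_tensor(x)).data
        assert np.abs(out1 - out2).max() > 1e-8


class TestConvLSTM:
    def test_zero_input_zero_bias_gives_zero(self):
        fuse = blocks.ConvLSTMFusion(2)
        fuse.cell.gates.bias.data[...] = 0.0
        z = nn.as_tensor(np.zeros((1, 2, 4, 4)))
        out = fuse(z, z)
        # gates at 0.5, g = tanh(0) = 0 -> c = 0, h = 0.5 * tanh(0) = 0
        np.testing.assert_array_equal(out.data, 0.0)

    def test_single_step_matches_gate_oracle(self):
        cell = blocks.ConvLSTMCell(1)
        x = RNG.normal(size=(1, 1, 2, 2))
        h0 = np.zeros((1, 1, 2, 2))
        out_h, out_c = cell.step(nn.as_tensor(x), nn.as_tensor(h0),
                                 nn.as_tensor(h0))
        z = direct_conv2d(np.concatenate([x[0], h0[0]]),
                          cell.gates.weight.data, cell.gates.bias.data)
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        i, f, o, g = sig(z[0]), sig(z[1]), sig(z[2]), np.tanh(z[3])
        c = i * g  # f * c0 = 0
        h = o * np.tanh(c)
        np.testing.assert_allclose(out_h.data[0, 0], h, atol=1e-5)
        np.testing.assert_allclose(out_c.data[0, 0], c, atol=1e-5)

    def test_two_step_sequence_matches_composed_oracle(self):
        cell = blocks.ConvLSTMCell(1)
        fuse = blocks.ConvLSTMFusion(1)
        fuse.cell.load_state_dict(cell.state_dict())
        skip = RNG.normal(size=(1, 1, 2, 2))
        up = RNG.normal(size=(1, 1, 2, 2))
        zeros = nn.as_tensor(np.zeros((1, 1, 2, 2)))
        h1, c1 = cell.step(nn.as_tensor(skip), zeros, zeros)
        h2, _ = cell.step(nn.as_tensor(up), h1, c1)
        np.testing.assert_allclose(
            fuse(nn.as_tensor(skip), nn.as_tensor(up)).data, h2.data,
            atol=1e-10)

    def test_dim_mismatch_rejected(self):
        fuse = blocks.ConvLSTMFusion(2)
        with pytest.raises(ValueError):
            fuse(nn.as_tensor(np.zeros((1, 2, 4, 4))),
                 nn.as_tensor(np.zeros((1, 2, 2, 2))))


class TestSepDilatedConv:
    def test_parameter_count_vs_full_conv(self):
        s = blocks.SepDilatedConv(32, 32, rate=2, bias=False)
        assert s.depthwise.weight.size + s.pointwise.weight.size == 1312
        assert 9 * 32 * 32 == 9216  # the full-conv count it replaces

    @pytest.mark.parametrize("rate", [1, 2, 4])
    def test_dims_preserved(self, rate):
        s = blocks.SepDilatedConv(3, 5, rate=rate)
        out = s(nn.as_tensor(RNG.normal(size=(1, 3, 6, 7))))
        assert out.shape == (1, 5, 6, 7)

    def test_rate_one_equals_plain_separable(self):
        s = blocks.SepDilatedConv(2, 2, rate=1)
        x = RNG.normal(size=(1, 2, 4, 4))
        dw = np.zeros((2, 2, 3, 3))
        for c in range(2):  # depthwise: each output sees only its channel
            dw[c, c] = s.depthwise.weight.data[c, 0]
        mid = direct_conv2d(x[0], dw, s.depthwise.bias.data)
        out = direct_conv2d(mid, s.pointwise.weight.data,
                            s.pointwise.bias.data)
        np.testing.assert_allclose(s(nn.as_tensor(x)).data[0],
                                   np.maximum(out, 0.0), atol=1e-5)


def test_all_blocks_preserve_spatial_dims():
    shapes = [(1, 4, 6, 6), (2, 4, 5, 9)]
    mods = [blocks.GCNBlock(4, 4), blocks.BoundaryRefine(4),
            blocks.PositionAttention(4), blocks.ChannelAttention(4),
            blocks.SepDilatedConv(4, 4, rate=2)]
    for shape in shapes:
        x = nn.as_tensor(RNG.normal(size=shape))
        for mod in mods:
            mod.eval()
            out = mod(x)
            assert out.shape[-2:] == shape[-2:], type(mod).__name__
            assert np.isfinite(out.data).all()
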