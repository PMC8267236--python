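"""Architecture tests: attention math against brute-force oracles, residual
identities, shape algebra, ablation switches and determinism."""

import numpy as np
import pytest

from aanet import nn
from aanet.network import (AANet, ChannelAttention, DAFBlock, EDSBlock,
                           MSCBlock, NetConfig, PositionalAttention, USBlock)


def brute_force_positional(x, wq, bq, wk, bk, wv, bv, alpha):
    """O(N^2) double loop over pixel pairs, straight from the definitions."""
    c, h, w = x.shape
    n = h * w
    proj = lambda wt, bias: np.array(
        [[(wt[o, :, 0, 0] * x[:, i // w, i % w]).sum() + bias[o]
          for i in range(n)] for o in range(wt.shape[0])])
    q, k, v = proj(wq, bq), proj(wk, bk), proj(wv, bv)
    s = np.zeros((n, n))
    for j in range(n):
        e = np.array([q[:, i] @ k[:, j] for i in range(n)])
        e = np.exp(e - e.max())
        s[j] = e / e.sum()
    ea = np.zeros((c, n))
    for j in range(n):
        for i in range(n):
            ea[:, j] += s[j, i] * v[:, i]
    ea = alpha * ea.reshape(c, h, w) + x
    return ea, s


def brute_force_channel(x, beta):
    c, h, w = x.shape
    xf = x.reshape(c, h * w)
    m = np.zeros((c, c))
    for j in range(c):
        e = np.array([xf[i] @ xf[j] for i in range(c)])
        e = np.exp(e - e.max())
        m[j] = e / e.sum()
    out = np.zeros_like(xf)
    for j in range(c):
        for i in range(c):
            out[j] += m[j, i] * xf[i]
    return beta * out.reshape(c, h, w) + x, m


class TestPositionalAttention:
    def test_rows_of_spatial_map_sum_to_one(self, rng):
        pa = PositionalAttention(8, scale_init=0.3, rng=rng)
        x = rng.normal(size=(5, 8, 4, 4)).astype(np.float32)
        _, s = pa(nn.Tensor(x))
        assert s.shape == (5, 16, 16)
        assert np.allclose(s.data.sum(axis=-1), 1.0, atol=1e-5)
        assert (s.data >= 0).all()

    def test_zero_scale_is_identity(self, rng):
        pa = PositionalAttention(4, scale_init=0.0, rng=rng)
        x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
        ea, _ = pa(nn.Tensor(x))
        assert np.array_equal(ea.data, x)

    @pytest.mark.parametrize("c,h,w", [(2, 2, 2), (8, 6, 6)])
    def test_matches_brute_force_loop(self, rng, c, h, w):
        pa = PositionalAttention(c, scale_init=0.7, rng=rng)
        x = rng.normal(size=(1, c, h, w))
        ea, s = pa(nn.Tensor(x))
        ref_ea, ref_s = brute_force_positional(
            x[0], pa.query.weight.data, pa.query.bias.data,
            pa.key.weight.data, pa.key.bias.data,
            pa.value.weight.data, pa.value.bias.data, 0.7)
        assert np.allclose(s.data[0], ref_s, atol=1e-5)
        assert np.allclose(ea.data[0], ref_ea, atol=1e-5)

    def test_empty_grid_rejected(self, rng):
        pa = PositionalAttention(2, rng=rng)
        with pytest.raises(ValueError):
            pa(nn.Tensor(np.zeros((1, 2, 0, 0))))


class TestChannelAttention:
    def test_rows_of_channel_map_sum_to_one(self, rng):
        ca = ChannelAttention(scale_init=0.4)
        x = rng.normal(size=(3, 6, 4, 4)).astype(np.float32)
        _, m = ca(nn.Tensor(x))
        assert m.shape == (3, 6, 6)
        assert np.allclose(m.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_zero_scale_is_identity(self, rng):
        ca = ChannelAttention(scale_init=0.0)
        x = rng.normal(size=(1, 3, 2, 2)).astype(np.float32)
        out, _ = ca(nn.Tensor(x))
        assert np.array_equal(out.data, x)

    @pytest.mark.parametrize("c,h,w", [(3, 2, 2), (8, 6, 6)])
    def test_matches_brute_force_loop(self, rng, c, h, w):
        ca = ChannelAttention(scale_init=0.9)
        x = rng.normal(size=(1, c, h, w))
        out, m = ca(nn.Tensor(x))
        ref_out, ref_m = brute_force_channel(x[0], 0.9)
        assert np.allclose(m.data[0], ref_m, atol=1e-5)
        assert np.allclose(out.data[0], ref_out, atol=1e-5)

    def test_permutation_equivariance(self, rng):
        """No convolutions in the head: permuting channels permutes outputs."""
        ca = ChannelAttention(scale_init=0.5)
        x = rng.normal(size=(1, 5, 3, 3))
        perm = rng.permutation(5)
        out, _ = ca(nn.Tensor(x))
        out_p, _ = ca(nn.Tensor(x[:, perm]))
        assert np.allclose(out_p.data, out.data[:, perm], atol=1e-6)


class TestBlocks:
    def test_eds_shape_contract(self, rng):
        eds = EDSBlock(4, 16, rng)
        h, a = eds(nn.Tensor(rng.normal(size=(2, 4, 16, 16)).astype(np.float32)))
        assert h.shape == (2, 16, 8, 8)
        assert a.shape == (2, 16, 16, 16)

    def test_eds_output_composes_from_submodules(self, rng):
        """h must equal maxpool(conv2(conv1(x)) + res(x)) exactly."""
        eds = EDSBlock(3, 8, rng).eval()
        x = nn.Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        h, _ = eds(x)
        g2 = eds.conv2(eds.conv1(x))
        ref = nn.maxpool2d(g2 + eds.res(x), 2)
        assert np.allclose(h.data, ref.data, atol=1e-6)

    def test_eds_zero_parameters_give_zero_output(self, rng):
        eds = EDSBlock(2, 4, rng)
        for p in eds.parameters():
            p.data[...] = 0.0
        h, a = eds(nn.Tensor(np.ones((1, 2, 4, 4), dtype=np.float32)))
        assert np.allclose(h.data, 0.0) and np.allclose(a.data, 0.0)

    def test_eds_odd_spatial_rejected(self, rng):
        eds = EDSBlock(2, 4, rng)
        with pytest.raises(ValueError, match="divisible"):
            eds(nn.Tensor(np.zeros((1, 2, 5, 6), dtype=np.float32)))

    def test_msc_preserves_shape_and_uses_stated_dilations(self, rng):
        msc = MSCBlock(16, (6, 12, 18), rng)
        out = msc(nn.Tensor(rng.normal(size=(1, 16, 40, 40)).astype(np.float32)))
        assert out.shape == (1, 16, 40, 40)
        assert [b.dilation for b in msc.branches] == [6, 12, 18]
        assert [b.padding for b in msc.branches] == [6, 12, 18]

    def test_msc_zero_input_zero_bias_gives_zero(self, rng):
        msc = MSCBlock(4, (6, 12, 18), rng)
        out = msc(nn.Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_daf_variants_share_io_shapes(self, rng):
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        shapes = set()
        for variant in ("DAF1", "DAF2", "DAF3"):
            daf = DAFBlock(8, 16, 3, variant, rng=rng)
            fused, aux = daf(nn.Tensor(x), (16, 16))
            shapes.add((fused.shape, aux.shape))
        assert shapes == {((1, 16, 4, 4), (1, 3, 16, 16))}

    def test_daf1_composes_from_attention_heads(self, rng):
        daf = DAFBlock(4, 8, 3, "DAF1", scale_init=0.5, rng=rng).eval()
        x = nn.Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        fused, _ = daf(x, (8, 8))
        y = daf.conv2(daf.conv1(x))
        ea, _ = daf.pa(y)
        ca, _ = daf.ca(y)
        ref = daf.fuse(ea + ca)
        assert np.allclose(fused.data, ref.data, atol=1e-6)

    def test_daf_attention_off_reduces_to_conv_path(self, rng):
        """With both scales zero the attention heads pass y through, so the
        fused output depends on the double-conv trunk alone."""
        daf = DAFBlock(4, 8, 3, "DAF1", scale_init=0.0, rng=rng).eval()
        x = nn.Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        fused, _ = daf(x, (8, 8))
        y = daf.conv2(daf.conv1(x))
        ref = daf.fuse(y + y)
        assert np.allclose(fused.data, ref.data, atol=1e-6)

    def test_daf_unknown_variant_rejected(self, rng):
        with pytest.raises(ValueError, match="variant"):
            DAFBlock(4, 8, 3, "DAF4", rng=rng)

    def test_us_shape_contract_and_mismatch_error(self, rng):
        us = USBlock(16, 8, 8, rng)
        prev = nn.Tensor(rng.normal(size=(1, 16, 4, 4)).astype(np.float32))
        skip = nn.Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        assert us(prev, skip).shape == (1, 8, 8, 8)
        with pytest.raises(ValueError, match="twice"):
            us(prev, nn.Tensor(np.zeros((1, 8, 6, 6), dtype=np.float32)))

    def test_us_zero_parameters_give_zero(self, rng):
        us = USBlock(4, 2, 2, rng)
        for p in us.parameters():
            p.data[...] = 0.0
        out = us(nn.Tensor(np.ones((1, 4, 2, 2), dtype=np.float32)),
                 nn.Tensor(np.ones((1, 2, 4, 4), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)


class TestAANet:
    def test_bundle_contract(self, rng):
        net = AANet(NetConfig(base_channels=4, seed=0))
        x = rng.normal(size=(1, 4, 32, 32)).astype(np.float32)
        b = net(x)
        assert len(b.eds_logits) == 4 and len(b.us_logits) == 4
        assert b.daf_logits is not None
        assert b.n_heads == 10
        for head in b.eds_logits + b.us_logits + [b.daf_logits, b.final_logits]:
            assert head.shape == (1, 3, 32, 32)

    @pytest.mark.parametrize("size", [32, 48, 64])
    def test_decoder_restores_input_resolution(self, rng, size):
        net = AANet(NetConfig(base_channels=4, seed=0))
        b = net(rng.normal(size=(1, 4, size, size)).astype(np.float32))
        assert b.final_logits.shape == (1, 3, size, size)

    def test_wrong_input_shape_rejected(self, rng):
        net = AANet(NetConfig(base_channels=4, seed=0))
        with pytest.raises(ValueError, match="divisible"):
            net(np.zeros((1, 4, 30, 30), dtype=np.float32))
        with pytest.raises(ValueError, match="expected"):
            net(np.zeros((1, 3, 32, 32), dtype=np.float32))

    def test_msc_disabled_everywhere_still_runs(self, rng):
        net = AANet(NetConfig(base_channels=4, msc_positions=(), seed=0))
        b = net(rng.normal(size=(1, 4, 32, 32)).astype(np.float32))
        assert b.final_logits.shape == (1, 3, 32, 32)
        assert all(m is None for m in net.msc)

    def test_supervision_switches_reduce_head_count(self, rng):
        cfg = NetConfig(base_channels=4, eds_supervision=False,
                        us_supervision=False, seed=0)
        b = AANet(cfg)(rng.normal(size=(1, 4, 32, 32)).astype(np.float32))
        assert b.eds_logits == [] and b.us_logits == []
        assert b.n_heads == 2  # bottleneck + final

    def test_eval_forward_deterministic(self, rng):
        net = AANet(NetConfig(base_channels=4, seed=0)).eval()
        x = rng.normal(size=(1, 4, 32, 32)).astype(np.float32)
        a, b = net(x), net(x)
        assert np.array_equal(a.final_logits.data, b.final_logits.data)

    def test_predict_regions_nesting_repair(self, rng):
        net = AANet(NetConfig(base_channels=4, seed=0))
        x = rng.normal(size=(2, 4, 32, 32)).astype(np.float32)
        masks = net.predict_regions(x, enforce_nesting=True)
        assert masks.shape == (2, 3, 32, 32)
        assert not (masks[:, 2] & ~masks[:, 1]).any()
        assert not (masks[:, 1] & ~masks[:, 0]).any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            NetConfig(daf_variant="DAF9")
        with pytest.raises(ValueError, match="MSC positions"):
            NetConfig(msc_positions=(0, 5))
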