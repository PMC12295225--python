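"""Linear attention algebra and the COKA block assembly."""

import numpy as np
import pytest

from ilvit.attention import (AttentionConfig, Block, BlockConfig,
                             MultiHeadPooledAttention, linear_attention)
from ilvit.tensor import Tensor


def sigm(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestLinearAttention:
    def test_single_token_closed_form(self, rng):
        d = 6
        q = rng.normal(size=(1, 1, d))
        k = rng.normal(size=(1, 1, d))
        v = rng.normal(size=(1, 1, d))
        out = linear_attention(Tensor(q), Tensor(k), Tensor(v), d).numpy()
        p = np.exp(v[0, 0] - v[0, 0].max())
        p /= p.sum()
        # σ(Q)(σ(Kᵀ)P): with one token the key–value summary is the outer
        # product σ(k)ᵀ p, so out_g = Σ_f σ(q_f) σ(k_f) p_g / √d
        expected = (sigm(q[0, 0]) * sigm(k[0, 0])).sum() * p / np.sqrt(d)
        np.testing.assert_allclose(out[0, 0], expected, atol=1e-10)

    def test_right_to_left_equals_left_to_right_association(self, rng):
        """Matrix associativity: σ(Q)(σ(Kᵀ)P) == (σ(Q)σ(Kᵀ))P on ≥20
        random instances."""
        for trial in range(20):
            r = np.random.default_rng(trial)
            q = r.normal(size=(2, 16, 8))
            k = r.normal(size=(2, 16, 8))
            v = r.normal(size=(2, 16, 8))
            got = linear_attention(Tensor(q), Tensor(k), Tensor(v), 8).numpy()
            p = np.exp(v - v.max(axis=-1, keepdims=True))
            p /= p.sum(axis=-1, keepdims=True)
            left = (sigm(q) @ sigm(k).swapaxes(-1, -2)) @ p / np.sqrt(8)
            np.testing.assert_allclose(got, left, atol=1e-5)

    def test_key_value_token_permutation_invariance(self, rng):
        q = Tensor(rng.normal(size=(1, 5, 4)))
        k = rng.normal(size=(1, 7, 4))
        v = rng.normal(size=(1, 7, 4))
        out = linear_attention(q, Tensor(k), Tensor(v), 4).numpy()
        perm = rng.permutation(7)
        out_p = linear_attention(q, Tensor(k[:, perm]), Tensor(v[:, perm]), 4).numpy()
        np.testing.assert_allclose(out, out_p, atol=1e-12)

    def test_no_token_mixing_through_query_gate(self, rng):
        """Changing query token t only affects output token t."""
        q = rng.normal(size=(1, 5, 4))
        k = Tensor(rng.normal(size=(1, 6, 4)))
        v = Tensor(rng.normal(size=(1, 6, 4)))
        base = linear_attention(Tensor(q), k, v, 4).numpy()
        q2 = q.copy()
        q2[0, 2] += 5.0
        out = linear_attention(Tensor(q2), k, v, 4).numpy()
        assert np.abs(out[0, 2] - base[0, 2]).max() > 1e-6
        mask = np.ones(5, dtype=bool)
        mask[2] = False
        np.testing.assert_allclose(out[0, mask], base[0, mask], atol=1e-12)

    def test_kv_token_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="token counts"):
            linear_attention(Tensor(np.zeros((1, 4, 4))),
                             Tensor(np.zeros((1, 5, 4))),
                             Tensor(np.zeros((1, 6, 4))), 4)

    def test_mac_count_grows_linearly_in_tokens(self):
        """Analytic profile: doubling L doubles the linear-attention MAC
        count, versus 4× for the quadratic softmax form."""
        def linear_macs(l, dk):
            return 2 * l * dk * dk

        def softmax_macs(l, dk):
            return 2 * l * l * dk

        assert linear_macs(128, 8) == 2 * linear_macs(64, 8)
        assert softmax_macs(128, 8) == 4 * softmax_macs(64, 8)


class TestMultiHead:
    def test_output_shape_preserved_without_pooling(self, rng):
        cfg = AttentionConfig(embed_dim=16, dim_out=16, num_heads=4,
                              attn_type="linear")
        mha = MultiHeadPooledAttention(cfg, rng)
        y, hw = mha(Tensor(rng.normal(size=(2, 16, 16))), (4, 4))
        assert y.shape == (2, 16, 16) and hw == (4, 4)

    def test_single_head_equals_manual_single_head_computation(self, rng):
        cfg = AttentionConfig(embed_dim=8, dim_out=8, num_heads=1,
                              attn_type="linear")
        mha = MultiHeadPooledAttention(cfg, rng)
        x = Tensor(rng.normal(size=(1, 9, 8)))
        y, _ = mha(x, (3, 3))
        # manual: project, pool (stride 1 depthwise), gate, mix, project
        def proj_pool(lin, pool):
            t = lin(x).numpy().reshape(1, 3, 3, 8).transpose(0, 3, 1, 2)
            g = Tensor(t).conv2d(pool.weight, None, stride=1, padding=1,
                                 groups=8).numpy()
            return g.transpose(0, 2, 3, 1).reshape(1, 9, 8)

        q = proj_pool(mha.wq, mha.pool_q)
        k = proj_pool(mha.wk, mha.pool_k)
        v = proj_pool(mha.wv, mha.pool_v)
        p = np.exp(v - v.max(axis=-1, keepdims=True))
        p /= p.sum(axis=-1, keepdims=True)
        inner = sigm(q) @ (sigm(k).swapaxes(-1, -2) @ p) / np.sqrt(8) + q
        ref = inner @ mha.proj.weight.data + mha.proj.bias.data
        np.testing.assert_allclose(y.numpy(), ref, atol=1e-8)


class TestCokaBlock:
    def cfg(self, **kw):
        base = dict(dim=8, dim_out=8, num_heads=2, attn_type="linear",
                    use_odc=True, norm="contranorm", ffn="kan",
                    odc_num_kernels=2, odc_group_width=4, kan_mode="channelwise")
        base.update(kw)
        return BlockConfig(**base)

    def test_shape_preserved_without_pooling(self, rng):
        block = Block(self.cfg(), rng)
        y, hw = block(Tensor(rng.normal(size=(2, 16, 8))), (4, 4))
        assert y.shape == (2, 16, 8) and hw == (4, 4)

    def test_zeroed_inner_paths_make_block_identity(self, rng):
        """With the attention output projection and the KAN branch zeroed,
        both residual paths reduce the block to the identity map."""
        block = Block(self.cfg(), rng)
        block.attn.proj.weight.data[:] = 0.0
        block.attn.proj.bias.data[:] = 0.0
        for layer in block.ffn.layers:
            layer.spline_coef.data[:] = 0.0
            layer.base_weight.data[:] = 0.0
        x = rng.normal(size=(2, 16, 8))
        y, _ = block(Tensor(x), (4, 4))
        np.testing.assert_allclose(y.numpy(), x, atol=1e-12)

    def test_matches_straight_line_composition_of_subops(self, rng):
        """Oracle: call the four sub-operations independently and compose."""
        block = Block(self.cfg(), rng)
        x = Tensor(rng.normal(size=(2, 16, 8)))
        y, _ = block(x, (4, 4))

        xn = block.norm1(x)
        grid = xn.reshape((2, 4, 4, 8)).transpose(0, 3, 1, 2)
        conv = block.odc(grid).transpose(0, 2, 3, 1).reshape((2, 16, 8))
        attn, _ = block.attn(conv, (4, 4))
        x1 = x + attn
        ref = x1 + block.ffn(block.norm2(x1))
        np.testing.assert_allclose(y.numpy(), ref.numpy(), atol=1e-6)

    def test_block_contracts_toward_identity_as_weights_shrink(self, rng):
        """Residual map: scaling the inner weights toward zero drives the
        block's deviation from identity to zero monotonically."""
        x = rng.normal(size=(1, 16, 8))
        devs = []
        for scale in (1.0, 0.1, 0.01):
            block = Block(self.cfg(), np.random.default_rng(3))
            block.attn.proj.weight.data *= scale
            block.attn.proj.bias.data *= scale
            for layer in block.ffn.layers:
                layer.spline_coef.data *= scale
                layer.base_weight.data *= scale
            y, _ = block(Tensor(x), (4, 4))
            devs.append(np.abs(y.numpy() - x).max())
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.05
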