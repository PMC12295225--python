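"""Dynamic Inception Convolution stem: kernel attention, dynamic
aggregation, the four-branch mixer, and the stem contract."""

import numpy as np
import pytest

from ilvit import nn
from ilvit.dic import (DICConfig, DICStem, DynamicKernelBank, InceptionMix,
                       aggregate_and_convolve, kernel_attention)
from ilvit.tensor import Tensor


def make_bank(rng, cin=8, cout=6, k=3, K=4, **kw):
    return DynamicKernelBank(cin, cout, k, rng, num_kernels=K, padding=1, **kw)


class TestKernelAttention:
    def test_weights_sum_to_one_and_nonnegative(self, rng):
        bank = make_bank(rng)
        w = kernel_attention(Tensor(rng.normal(size=(5, 8, 6, 6))), bank).numpy()
        assert w.shape == (5, 4)
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_logits_give_uniform_weights(self, rng):
        bank = make_bank(rng)
        bank.fc2.weight.data[:] = 0.0      # forced equal logits
        bank.fc2.bias.data[:] = 3.0
        w = kernel_attention(Tensor(rng.normal(size=(3, 8, 4, 4))), bank).numpy()
        np.testing.assert_allclose(w, 0.25, atol=1e-12)

    def test_single_kernel_degenerates_to_one(self, rng):
        bank = make_bank(rng, K=1)
        w = kernel_attention(Tensor(rng.normal(size=(2, 8, 4, 4))), bank).numpy()
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_matches_straight_line_recomputation(self, rng):
        """Independent oracle: explicit global mean, two matrix products,
        softmax — no shared code path."""
        bank = make_bank(rng, cin=8, cout=4)
        x = rng.normal(size=(2, 8, 16, 16))
        w = kernel_attention(Tensor(x), bank).numpy()
        pooled = x.mean(axis=(2, 3))
        h = pooled @ bank.fc1.weight.data + bank.fc1.bias.data
        logits = h @ bank.fc2.weight.data + bank.fc2.bias.data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        np.testing.assert_allclose(w, e / e.sum(axis=1, keepdims=True), atol=1e-6)

    def test_channel_mismatch_names_expectation(self, rng):
        bank = make_bank(rng, cin=8)
        with pytest.raises(ValueError, match="8"):
            kernel_attention(Tensor(np.zeros((1, 5, 4, 4))), bank)


class TestAggregateAndConvolve:
    def test_one_hot_weights_select_single_kernel(self, rng):
        bank = make_bank(rng)
        x = Tensor(rng.normal(size=(2, 8, 6, 6)))
        onehot = np.zeros((2, 4))
        onehot[:, 2] = 1.0
        got = aggregate_and_convolve(x, bank, Tensor(onehot)).numpy()
        ref = x.conv2d(bank.kernels[2], bank.bias, padding=1).numpy()
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_linearity_equals_weighted_sum_of_convolutions(self, rng):
        """By linearity the blended-kernel output must match K separate
        convolutions combined with the same weights."""
        bank = make_bank(rng)
        x = Tensor(rng.normal(size=(3, 8, 6, 6)))
        w = rng.dirichlet(np.ones(4), size=3)
        got = aggregate_and_convolve(x, bank, Tensor(w)).numpy()
        ref = sum(
            w[:, k][:, None, None, None]
            * x.conv2d(bank.kernels[k], None, padding=1).numpy()
            for k in range(4)
        ) + bank.bias.data[None, :, None, None]
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_per_sample_blending_differs_from_mean_weights(self, rng):
        """Each sample is convolved with its own blended kernel."""
        bank = make_bank(rng)
        x = rng.normal(size=(2, 8, 6, 6))
        w = np.array([[1.0, 0, 0, 0], [0, 0, 0, 1.0]])
        got = aggregate_and_convolve(Tensor(x), bank, Tensor(w)).numpy()
        for i in range(2):
            per = Tensor(x[i : i + 1]).conv2d(
                bank.kernels[np.argmax(w[i])], bank.bias, padding=1).numpy()
            np.testing.assert_allclose(got[i], per[0], atol=1e-10)
        mean_w = np.repeat(w.mean(axis=0, keepdims=True), 2, axis=0)
        blended = aggregate_and_convolve(Tensor(x), bank, Tensor(mean_w)).numpy()
        assert np.abs(got - blended).max() > 1e-3


class TestInceptionMix:
    def test_identity_branch_is_bit_identical_and_channels_conserved(self, rng):
        cfg = DICConfig(embed_dim=16, branch_ratios=(0.25, 0.25, 0.25, 0.25))
        mix = InceptionMix(16, cfg, rng)
        x = rng.normal(size=(2, 16, 7, 7))
        y = mix(Tensor(x)).numpy()
        assert y.shape == x.shape
        np.testing.assert_array_equal(y[:, 12:], x[:, 12:])   # identity slice

    def test_branches_match_nested_loop_depthwise_oracle(self, rng):
        cfg = DICConfig(embed_dim=8, branch_ratios=(0.25, 0.25, 0.25, 0.25))
        mix = InceptionMix(8, cfg, rng)
        x = rng.normal(size=(1, 8, 5, 5))
        y = mix(Tensor(x)).numpy()

        def dw_loop(xc, kernel, bias):
            kh, kw = kernel.shape
            ph, pw = kh // 2, kw // 2
            xp = np.pad(xc, ((ph, ph), (pw, pw)))
            out = np.zeros_like(xc)
            for i in range(xc.shape[0]):
                for j in range(xc.shape[1]):
                    out[i, j] = (xp[i : i + kh, j : j + kw] * kernel).sum() + bias
            return out

        for c in range(2):   # square branch channels
            ref = dw_loop(x[0, c], mix.conv_square.weight.data[c, 0],
                          mix.conv_square.bias.data[c])
            np.testing.assert_allclose(y[0, c], ref, atol=1e-6)
        for c in range(2):   # horizontal band branch
            ref = dw_loop(x[0, 2 + c], mix.conv_hband.weight.data[c, 0],
                          mix.conv_hband.bias.data[c])
            np.testing.assert_allclose(y[0, 2 + c], ref, atol=1e-6)
        for c in range(2):   # vertical band branch
            ref = dw_loop(x[0, 4 + c], mix.conv_vband.weight.data[c, 0],
                          mix.conv_vband.bias.data[c])
            np.testing.assert_allclose(y[0, 4 + c], ref, atol=1e-6)

    def test_invalid_split_raises(self):
        cfg = DICConfig(branch_ratios=(0.5, 0.5, 0.0, 0.0))
        with pytest.raises(ValueError, match="split"):
            cfg.branch_channels(3)     # rounded shares exceed the channels


class TestDICStem:
    def test_shape_contract_224_to_56(self, rng):
        stem = DICStem(DICConfig(), rng)
        y = stem(Tensor(rng.normal(size=(2, 3, 224, 224))))
        assert y.shape == (2, 96, 56, 56)
        assert np.isfinite(y.numpy()).all()

    def test_indivisible_input_raises(self, rng):
        stem = DICStem(DICConfig(), rng)
        with pytest.raises(ValueError, match="stride"):
            stem(Tensor(np.zeros((1, 3, 225, 225))))

    def test_fewer_parameters_than_k_dense_large_kernels(self, rng):
        """The stem must undercut K dense copies of a 7×7 stride-4
        projection (it replaces large kernels with fewer parameters) —
        and in fact undercuts even a single copy."""
        cfg = DICConfig()
        stem = DICStem(cfg, rng)
        dense_7x7 = cfg.embed_dim * 3 * 49 + cfg.embed_dim
        assert stem.n_params() < cfg.num_kernels * dense_7x7
        assert stem.n_params() < dense_7x7

    def test_gradients_reach_all_kernels_and_subnet(self, rng):
        stem = DICStem(DICConfig(embed_dim=16,
                                 branch_ratios=(0.25, 0.25, 0.25, 0.25)), rng)
        out = stem(Tensor(rng.normal(size=(2, 3, 16, 16))))
        (out * out).mean().backward()
        bank = stem.proj
        grads = np.linalg.norm(bank.kernels.grad.reshape(bank.num_kernels, -1), axis=1)
        assert (grads > 0).all(), "every candidate kernel must receive gradient"
        assert np.linalg.norm(bank.fc1.weight.grad) > 0
        assert np.linalg.norm(bank.fc2.weight.grad) > 0
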