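"""Gated transformer encoder: attention oracles, gate behaviour, invariants."""

import numpy as np
import pytest

from adfuse._nn import Parameter
from adfuse._tensor import Tensor, no_grad
from adfuse.attention import (ConvQKV, EncoderBlock, MultiHeadSelfAttention,
                              TransformerConfig, TransformerEncoder,
                              feed_forward, gated_residual,
                              single_head_attention)

rng = np.random.default_rng(7)


def brute_force_attention(q, k, v, d):
    """Independent straight-line softmax(QK^T/sqrt(d))V."""
    scores = q @ k.T / np.sqrt(d)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    w = e / e.sum(axis=1, keepdims=True)
    return w @ v, w


class TestSingleHeadAttention:
    def test_single_token_weight_is_one(self):
        q = Tensor(rng.normal(size=(1, 1, 2)).astype(np.float32))
        k = Tensor(rng.normal(size=(1, 1, 2)).astype(np.float32))
        v = Tensor(rng.normal(size=(1, 1, 2)).astype(np.float32))
        out, attn = single_head_attention(q, k, v, 2)
        np.testing.assert_allclose(attn.data, [[[1.0]]], atol=1e-7)
        np.testing.assert_allclose(out.data, v.data, atol=1e-7)

    def test_zero_query_gives_uniform_weights_and_column_mean(self):
        n = 4
        k = Tensor(rng.normal(size=(1, n, 2)).astype(np.float32))
        v = Tensor(rng.normal(size=(1, n, 2)).astype(np.float32))
        out, attn = single_head_attention(Tensor(np.zeros((1, n, 2), np.float32)),
                                          k, v, 2)
        np.testing.assert_allclose(attn.data, 1.0 / n, atol=1e-6)
        np.testing.assert_allclose(out.data[0], np.tile(v.data[0].mean(0), (n, 1)),
                                   atol=1e-6)

    def test_matches_brute_force_oracle(self):
        q, k, v = (rng.normal(size=(4, 2)) for _ in range(3))
        out, attn = single_head_attention(Tensor(q[None]), Tensor(k[None]),
                                          Tensor(v[None]), 2)
        exp_out, exp_w = brute_force_attention(q, k, v, 2)
        np.testing.assert_allclose(out.data[0], exp_out, atol=1e-6)
        np.testing.assert_allclose(attn.data[0], exp_w, atol=1e-6)


class TestConvQKV:
    def _proj(self, n):
        return ConvQKV(n, np.random.default_rng(0))

    def test_identity_projection_returns_input(self):
        proj = self._proj(4)
        proj.weight.data = np.eye(4, dtype=np.float32)
        proj.bias.data[:] = 0.0
        x = rng.normal(size=(2, 4, 8)).astype(np.float32)
        np.testing.assert_allclose(proj(Tensor(x)).data, x, atol=1e-7)

    def test_equals_per_voxel_channel_mixing_oracle(self):
        proj = self._proj(5)
        x = rng.normal(size=(1, 5, 3)).astype(np.float32)
        out = proj(Tensor(x)).data
        # oracle: at every voxel position, output channels = W @ input channels
        for voxel in range(3):
            expected = proj.weight.data @ x[0, :, voxel] + proj.bias.data[:, 0]
            np.testing.assert_allclose(out[0, :, voxel], expected, atol=1e-5)

    def test_zero_kernel_gives_zero(self):
        proj = self._proj(4)
        proj.weight.data[:] = 0.0
        proj.bias.data[:] = 0.0
        out = proj(Tensor(rng.normal(size=(1, 4, 8)).astype(np.float32)))
        assert np.all(out.data == 0.0)


class TestMultiHead:
    def test_single_head_config_matches_plain_attention(self):
        cfg = TransformerConfig(n_layers=1, n_heads=1, token_dim=4, n_tokens=6)
        msa = MultiHeadSelfAttention(cfg, np.random.default_rng(1))
        x = rng.normal(size=(1, 6, 4)).astype(np.float32)
        out, attn = msa(Tensor(x))
        q = msa.q0(Tensor(x))
        k = msa.k0(Tensor(x))
        v = msa.v0(Tensor(x))
        exp_out, exp_attn = single_head_attention(q, k, v, cfg.attn_scale_d)
        np.testing.assert_allclose(out.data, exp_out.data, atol=1e-6)
        np.testing.assert_allclose(attn[:, 0], exp_attn.data, atol=1e-6)

    def test_default_head_geometry(self):
        cfg = TransformerConfig()  # H=4, d=8 -> head dim 2
        assert cfg.head_dim == 2
        msa = MultiHeadSelfAttention(
            TransformerConfig(n_tokens=10), np.random.default_rng(0))
        out, attn = msa(Tensor(rng.normal(size=(2, 10, 8)).astype(np.float32)))
        assert out.shape == (2, 10, 8)  # concat restores d
        assert attn.shape == (2, 4, 10, 10)

    def test_tied_head_projections_give_identical_heads(self):
        cfg = TransformerConfig(n_heads=4, token_dim=8, n_tokens=5)
        msa = MultiHeadSelfAttention(cfg, np.random.default_rng(2))
        ref_state = {"q": msa.q0, "k": msa.k0, "v": msa.v0}
        for h in range(1, 4):
            for name in ("q", "k", "v"):
                getattr(msa, f"{name}{h}").weight.data = \
                    ref_state[name].weight.data.copy()
                getattr(msa, f"{name}{h}").bias.data = \
                    ref_state[name].bias.data.copy()
        # per-head slices differ, but tying projections makes every head's
        # ATTENTION identical only if slices coincide; check via equal slices
        for h in range(4):
            for name in ("q", "k", "v"):
                np.testing.assert_array_equal(
                    getattr(msa, f"{name}{h}").weight.data,
                    ref_state[name].weight.data)
        x = rng.normal(size=(1, 5, 8)).astype(np.float32)
        _, attn = msa(Tensor(x))
        # oracle: head h attention from the shared projection's slice h
        mixed_q = ref_state["q"](Tensor(x)).data
        mixed_k = ref_state["k"](Tensor(x)).data
        for h in range(4):
            sl = slice(2 * h, 2 * h + 2)
            _, exp = brute_force_attention(mixed_q[0][:, sl], mixed_k[0][:, sl],
                                           np.zeros((5, 2)), cfg.attn_scale_d)
            np.testing.assert_allclose(attn[0, h], exp, atol=1e-5)


class TestGateAndFFN:
    def test_zero_gate_masks_attention_branch(self):
        x = Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32))
        o = Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32))
        out = gated_residual(o, x, Tensor(np.float32(0.0)))
        np.testing.assert_array_equal(out.data, x.data)

    def test_full_gate_with_zero_output_is_identity(self):
        x = Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32))
        out = gated_residual(Tensor(np.zeros((2, 3, 4), np.float32)), x,
                             Tensor(np.float32(1.0)))
        np.testing.assert_array_equal(out.data, x.data)

    def test_gate_initialized_at_zero_and_clamped(self):
        block = EncoderBlock(TransformerConfig(n_tokens=4), np.random.default_rng(0))
        assert float(block.alpha.data) == 0.0
        assert block.alpha.clamp == (0.0, 1.0)

    def test_ffn_identity_weights_pass_nonnegative_input(self):
        d = 4
        x = np.abs(rng.normal(size=(1, 3, d))).astype(np.float32)
        out = feed_forward(Tensor(x), Tensor(np.eye(d, dtype=np.float32)),
                           Tensor(np.zeros(d, np.float32)),
                           Tensor(np.eye(d, dtype=np.float32)),
                           Tensor(np.zeros(d, np.float32)))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_ffn_identity_weights_rectify_negative_input(self):
        d = 3
        x = rng.normal(size=(2, 2, d)).astype(np.float32)
        out = feed_forward(Tensor(x), Tensor(np.eye(d, dtype=np.float32)),
                           Tensor(np.zeros(d, np.float32)),
                           Tensor(np.eye(d, dtype=np.float32)),
                           Tensor(np.zeros(d, np.float32)))
        np.testing.assert_allclose(out.data, np.maximum(x, 0.0), atol=1e-6)

    def test_ffn_matches_two_layer_oracle(self):
        d, hidden = 3, 5
        x = rng.normal(size=(1, 4, d))
        w1 = rng.normal(size=(d, hidden))
        b1 = rng.normal(size=hidden)
        w2 = rng.normal(size=(hidden, d))
        b2 = rng.normal(size=d)
        out = feed_forward(Tensor(x), Tensor(w1), Tensor(b1), Tensor(w2),
                           Tensor(b2))
        expected = np.maximum(x @ w1 + b1, 0.0) @ w2 + b2
        np.testing.assert_allclose(out.data, expected, atol=1e-6)


def straight_line_block(x, block):
    """Independent NumPy evaluation of one pre-norm gated encoder block."""
    def layer_norm(z, gamma, beta, eps=1e-5):
        mu = z.mean(-1, keepdims=True)
        var = ((z - mu) ** 2).mean(-1, keepdims=True)
        return (z - mu) / np.sqrt(var + eps) * gamma + beta

    cfg = block.cfg
    h = layer_norm(x, block.norm1.gamma.data, block.norm1.beta.data)
    heads = []
    dh = cfg.head_dim
    for i in range(cfg.n_heads):
        def mix(proj):
            return (proj.weight.data @ h[0] + proj.bias.data)[None]
        q = mix(getattr(block.msa, f"q{i}"))[0][:, i * dh:(i + 1) * dh]
        k = mix(getattr(block.msa, f"k{i}"))[0][:, i * dh:(i + 1) * dh]
        v = mix(getattr(block.msa, f"v{i}"))[0][:, i * dh:(i + 1) * dh]
        out, _ = brute_force_attention(q, k, v, cfg.attn_scale_d)
        heads.append(out)
    o = np.concatenate(heads, axis=-1)[None]
    x = float(block.alpha.data) * o + x
    h2 = layer_norm(x, block.norm2.gamma.data, block.norm2.beta.data)
    ffn = np.maximum(h2 @ block.ffn.w1.data + block.ffn.b1.data, 0.0) \
        @ block.ffn.w2.data + block.ffn.b2.data
    return ffn + x


class TestEncoderStack:
    def test_attention_rows_stochastic_and_nonnegative(self):
        cfg = TransformerConfig(n_layers=2, n_tokens=12)
        enc = TransformerEncoder(cfg, np.random.default_rng(3))
        x = rng.normal(size=(2, 12, 8)).astype(np.float32)
        with no_grad():
            _, stack = enc(Tensor(x))
        assert stack.n_layers == 2
        for layer in stack.layers:
            assert layer.shape == (2, 4, 12, 12)
            assert np.all(layer >= 0.0)
            np.testing.assert_allclose(layer.sum(-1), 1.0, atol=1e-5)

    def test_forward_is_deterministic(self):
        cfg = TransformerConfig(n_tokens=6)
        enc = TransformerEncoder(cfg, np.random.default_rng(4))
        x = Tensor(rng.normal(size=(1, 6, 8)).astype(np.float32))
        with no_grad():
            a, _ = enc(x)
            b, _ = enc(x)
        np.testing.assert_array_equal(a.data, b.data)

    def test_block_forward_matches_straight_line_oracle(self):
        cfg = TransformerConfig(n_layers=1, n_heads=2, token_dim=4, n_tokens=4)
        block = EncoderBlock(cfg, np.random.default_rng(5))
        block.alpha.data = np.float32(0.37)  # exercise a non-trivial gate
        x = rng.normal(size=(1, 4, 4)).astype(np.float32)
        with no_grad():
            out, _ = block(Tensor(x))
        expected = straight_line_block(x.astype(np.float64), block)
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_zero_gates_reduce_to_ffn_only_path(self):
        """With alpha = 0 the block equals the same block with MSA deleted."""
        cfg = TransformerConfig(n_layers=2, n_tokens=8)
        enc = TransformerEncoder(cfg, np.random.default_rng(6))
        x = Tensor(rng.normal(size=(1, 8, 8)).astype(np.float32))
        with no_grad():
            full, _ = enc(x)
            # MSA-ablated path reusing the same sub-modules
            h = x
            for block in enc.blocks:
                h = block.ffn(block.norm2(h)) + h
        np.testing.assert_array_equal(full.data, h.data)

    def test_typical_variant_has_positional_embedding_and_no_gate(self):
        cfg = TransformerConfig(n_tokens=5, variant="typical")
        enc = TransformerEncoder(cfg, np.random.default_rng(7))
        assert isinstance(enc.pos_embed, Parameter)
        assert all(b.alpha is None for b in enc.blocks)
        assert enc.gates() == [1.0, 1.0]

    def test_token_dim_must_divide_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerConfig(token_dim=6, n_heads=4)

    def test_attention_stack_json_sidecar_round_trip(self, tmp_path):
        from adfuse.attention import AttentionStack
        stack = AttentionStack()
        for _ in range(2):
            w = rng.random((1, 2, 3, 3)).astype(np.float32)
            stack.append(w / w.sum(-1, keepdims=True))
        path = tmp_path / "attention.json"
        stack.save(path)
        back = AttentionStack.load(path)
        assert back.n_layers == 2
        for a, b in zip(stack.layers, back.layers):
            np.testing.assert_allclose(a, b, atol=1e-7)
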