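"""Gated Transformer encoder over CNN feature-map tokens.

Each of the N feature maps from the convolutional encoder is one token; its
voxels, flattened, give the embedding (N = 200 tokens of dim d = 8 at the
default geometry).  The encoder differs from a stock pre-norm ViT block in
two ways:

* Q/K/V are produced by 1x1x1 convolutions over the channel (token) axis —
  per-voxel linear channel mixing — rather than per-token linear maps, and no
  positional embedding is added (the convolutional stack already encodes
  position).
* The attention branch of the first residual connection is scaled by a
  learnable scalar gate ``alpha`` per block, initialized at 0 and clamped to
  [0, 1] after every optimizer step: self-attention is masked at the start of
  training and introduced progressively as the gate opens.  The FFN residual
  is not gated.

A ``typical`` variant (ablation) restores linear Q/K/V projections, a learned
positional embedding, and an ungated (alpha = 1) residual.

Because a single Adam step moves a scalar by at most ~lr, a gate trained at
the base learning rate could never traverse [0, 1] within a normal training
budget; the gate therefore carries a learning-rate multiplier
(``gate_lr_mult``, default 100) consistent with the gate saturating near 1 by
the end of training.

All per-head row-stochastic attention matrices are recorded on the forward
pass for attention-rollout interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import LayerNorm, Linear, Module, Parameter, he_init
from ._tensor import Tensor, concat

__all__ = [
    "TransformerConfig", "AttentionStack", "single_head_attention",
    "feed_forward", "gated_residual", "ConvQKV", "LinearQKV",
    "MultiHeadSelfAttention", "FeedForward", "EncoderBlock",
    "TransformerEncoder",
]


@dataclass
class TransformerConfig:
    """Shape and variant of the transformer encoder.

    ``scale_dim`` selects the d used in the 1/sqrt(d) attention scaling:
    ``"head"`` uses the per-head key dimension (d/H, the default), ``"token"``
    the full token dimension.
    """

    n_layers: int = 2
    n_heads: int = 4
    token_dim: int = 8
    n_tokens: int = 200
    ffn_dim: int | None = None  # defaults to 4 * token_dim
    variant: str = "conv"  # "conv" (gated, conv QKV) or "typical"
    scale_dim: str = "head"
    gate_lr_mult: float = 100.0

    def __post_init__(self):
        if self.token_dim % self.n_heads:
            raise ValueError(
                f"token dim {self.token_dim} not divisible by {self.n_heads} heads")
        if self.variant not in ("conv", "typical"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.scale_dim not in ("head", "token"):
            raise ValueError(f"unknown scale_dim {self.scale_dim!r}")
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.token_dim

    @property
    def head_dim(self) -> int:
        return self.token_dim // self.n_heads

    @property
    def attn_scale_d(self) -> int:
        return self.head_dim if self.scale_dim == "head" else self.token_dim


@dataclass
class AttentionStack:
    """Per-layer, per-head attention matrices recorded on a forward pass.

    ``layers[l]`` has shape (B, H, N, N); every row is a softmax output and
    therefore sums to 1.
    """

    layers: list[np.ndarray] = field(default_factory=list)

    def append(self, mats: np.ndarray) -> None:
        self.layers.append(np.asarray(mats))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def as_array(self) -> np.ndarray:
        """(L, B, H, N, N) array."""
        return np.stack(self.layers, axis=0)

    def for_sample(self, b: int) -> np.ndarray:
        """(L, H, N, N) stack for one subject in the batch."""
        return np.stack([layer[b] for layer in self.layers], axis=0)

    def save(self, path) -> None:
        """Write the recorded matrices as a JSON sidecar for visualization."""
        import json
        payload = {"n_layers": self.n_layers,
                   "layers": [layer.tolist() for layer in self.layers]}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "AttentionStack":
        import json
        with open(path) as fh:
            payload = json.load(fh)
        stack = cls()
        for layer in payload["layers"]:
            stack.append(np.asarray(layer, dtype=np.float32))
        return stack


def single_head_attention(q: Tensor, k: Tensor, v: Tensor, d: int
                          ) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention: SoftMax(QK^T / sqrt(d)) V.

    Returns (output tokens, attention weights); rows of the weights sum to 1.
    """
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(float(d)))
    attn = scores.softmax(axis=-1)
    return attn @ v, attn


def gated_residual(out: Tensor, x: Tensor, alpha: Tensor) -> Tensor:
    """X' = alpha * O + X (the progressively unmasked attention residual)."""
    if out.shape != x.shape:
        raise ValueError(f"shape mismatch: {out.shape} vs {x.shape}")
    return alpha * out + x


def feed_forward(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """FFN(X) = max(0, X W1 + b1) W2 + b2."""
    return (x @ w1 + b1).relu() @ w2 + b2


class ConvQKV(Module):
    """Per-head Q/K/V via 1x1x1 convolution over the channel (token) axis.

    A 1x1x1 conv over N channels is exactly a per-voxel linear mixing of the
    N token rows, i.e. left-multiplication of the (N, d) token matrix by an
    (N, N) weight matrix plus a per-channel bias.  Each head keeps its own
    slice of width d/H of the mixed token matrix.
    """

    def __init__(self, n_tokens: int, rng: np.random.Generator):
        super().__init__()
        n = n_tokens
        self.weight = Parameter(he_init_matrix(rng, n))
        self.bias = Parameter(np.zeros((n, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, N, d) -> (B, N, d)
        return self.weight @ x + self.bias


def he_init_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(1.0 / n), size=(n, n)).astype(np.float32)


class LinearQKV(Module):
    """Stock per-token linear projection to a head subspace (d -> d/H)."""

    def __init__(self, d: int, dh: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(d, dh, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(x)


class MultiHeadSelfAttention(Module):
    """H parallel attention heads whose outputs are concatenated.

    With the ``conv`` variant each head owns three 1x1x1-conv projections
    producing full (N, d) mixes, of which the head keeps its d/H-wide slice;
    with ``typical`` each head owns three linear d -> d/H projections.
    """

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        dh = cfg.head_dim
        for h in range(cfg.n_heads):
            for name in ("q", "k", "v"):
                if cfg.variant == "conv":
                    proj = ConvQKV(cfg.n_tokens, rng)
                else:
                    proj = LinearQKV(cfg.token_dim, dh, rng)
                setattr(self, f"{name}{h}", proj)

    def forward(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        """x: (B, N, d) -> (concat head outputs (B, N, d), attention (B, H, N, N))."""
        cfg = self.cfg
        dh = cfg.head_dim
        outs, attns = [], []
        for h in range(cfg.n_heads):
            q = getattr(self, f"q{h}")(x)
            k = getattr(self, f"k{h}")(x)
            v = getattr(self, f"v{h}")(x)
            if cfg.variant == "conv":
                sl = slice(h * dh, (h + 1) * dh)
                q, k, v = q[:, :, sl], k[:, :, sl], v[:, :, sl]
            out, attn = single_head_attention(q, k, v, cfg.attn_scale_d)
            outs.append(out)
            attns.append(attn.data)
        o = concat(outs, axis=-1)
        return o, np.stack(attns, axis=1)


class FeedForward(Module):
    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.w1 = Parameter(he_init(rng, (d, hidden), d))
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32))
        self.w2 = Parameter(he_init(rng, (hidden, d), hidden))
        self.b2 = Parameter(np.zeros(d, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return feed_forward(x, self.w1, self.b1, self.w2, self.b2)


class EncoderBlock(Module):
    """Pre-norm block: x + alpha*MSA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.norm1 = LayerNorm(cfg.token_dim)
        self.msa = MultiHeadSelfAttention(cfg, rng)
        self.norm2 = LayerNorm(cfg.token_dim)
        self.ffn = FeedForward(cfg.token_dim, cfg.ffn_dim, rng)
        if cfg.variant == "conv":
            # learnable gate, 0 at init, projected back into [0,1] after updates
            self.alpha = Parameter(np.zeros((), dtype=np.float32), clamp=(0.0, 1.0),
                                   lr_scale=cfg.gate_lr_mult)
        else:
            self.alpha = None  # ungated residual (alpha identically 1)

    def gate_value(self) -> float:
        return 1.0 if self.alpha is None else float(self.alpha.data)

    def forward(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        o, attn = self.msa(self.norm1(x))
        if self.alpha is not None:
            x = gated_residual(o, x, self.alpha)
        else:
            x = o + x
        x = self.ffn(self.norm2(x)) + x
        return x, attn


class TransformerEncoder(Module):
    """L stacked encoder blocks, shared by both modalities.

    Returns the transformed tokens and an :class:`AttentionStack` holding the
    per-layer, per-head attention matrices of this forward pass.
    """

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        if cfg.variant == "typical":
            self.pos_embed = Parameter(
                rng.normal(0.0, 0.02, size=(cfg.n_tokens, cfg.token_dim))
                .astype(np.float32))
        else:
            self.pos_embed = None
        self.blocks: list[EncoderBlock] = []
        for i in range(cfg.n_layers):
            block = EncoderBlock(cfg, rng)
            setattr(self, f"layer{i}", block)
            self.blocks.append(block)

    def gates(self) -> list[float]:
        return [b.gate_value() for b in self.blocks]

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionStack]:
        if self.pos_embed is not None:
            x = x + self.pos_embed
        stack = AttentionStack()
        for block in self.blocks:
            x, attn = block(x)
            stack.append(attn)
        return x, stack
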