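"""End-to-end two-stream fusion model.

sMRI and PET volumes pass through independent 3D CNN encoders; the resulting
feature-map tokens pass through one shared gated Transformer; the transformed
tokens of both modalities are flattened, concatenated, and classified by a
two-layer MLP with SoftMax output.  Ablations: ``typical_transformer``
(linear Q/K/V, positional embedding, ungated residual) and ``cnn_only``
(encoder features go straight to the MLP; no attention is recorded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Dropout, Linear, Module
from ._tensor import Tensor, concat, cross_entropy_logits, no_grad
from .attention import AttentionStack, TransformerConfig, TransformerEncoder
from .encoder import Encoder3D, EncoderConfig
from .volumes import LABELS, Subject

__all__ = [
    "FusionConfig", "Prediction", "FusionNet", "assemble_model", "loss",
    "batch_loss", "subjects_to_array", "predict_batch", "save_checkpoint",
    "load_checkpoint",
]

ABLATIONS = ("full", "typical_transformer", "cnn_only")


@dataclass
class FusionConfig:
    """Classification-head settings and the ablation switch."""

    mlp_hidden: int = 256
    dropout_p: float = 0.1
    n_classes: int = 2
    ablation: str = "full"

    def __post_init__(self):
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")


@dataclass
class Prediction:
    """Class probabilities, the argmax label, and per-modality attention."""

    probs: np.ndarray
    label: str
    attention: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def y(self) -> int:
        return int(np.argmax(self.probs))


class MLPHead(Module):
    """Two linear transformations, dropout (p=0.1) after each, ReLU between."""

    def __init__(self, in_dim: int, hidden: int, n_classes: int, dropout_p: float,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, hidden, rng)
        self.drop1 = Dropout(dropout_p, rng)
        self.fc2 = Linear(hidden, n_classes, rng)
        self.drop2 = Dropout(dropout_p, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.drop1(self.fc1(x).relu())
        return self.drop2(self.fc2(x))


class FusionNet(Module):
    """The assembled two-stream model (see module docstring)."""

    def __init__(self, enc_cfg: EncoderConfig, tx_cfg: TransformerConfig,
                 fus_cfg: FusionConfig, grid: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        extent = enc_cfg.output_extent(grid)
        token_dim = extent ** 3
        if tx_cfg.n_tokens != enc_cfg.final_filters:
            raise ValueError(
                f"token count mismatch: transformer expects {tx_cfg.n_tokens} "
                f"tokens but the encoder emits {enc_cfg.final_filters} maps")
        if fus_cfg.ablation != "cnn_only" and tx_cfg.token_dim != token_dim:
            raise ValueError(
                f"token dim mismatch: transformer expects d={tx_cfg.token_dim} "
                f"but encoder maps flatten to {token_dim} (extent {extent}^3)")
        self.enc_cfg = enc_cfg
        self.tx_cfg = tx_cfg
        self.fus_cfg = fus_cfg
        self.grid = grid
        self.seed = seed
        self.encoder_smri = Encoder3D(enc_cfg, rng)
        self.encoder_pet = Encoder3D(enc_cfg, rng)
        if fus_cfg.ablation == "cnn_only":
            self.transformer = None
        else:
            # one transformer serves both modality streams
            self.transformer = TransformerEncoder(tx_cfg, rng)
        in_dim = 2 * enc_cfg.final_filters * token_dim
        self.head = MLPHead(in_dim, fus_cfg.mlp_hidden, fus_cfg.n_classes,
                            fus_cfg.dropout_p, rng)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor
                ) -> tuple[Tensor, dict[str, AttentionStack]]:
        """x: (B, 2, g, g, g) with channel 0 = sMRI, 1 = PET.

        Returns (logits (B, n_classes), {"smri": AttentionStack, "pet": ...});
        the attention dict is empty for the cnn_only ablation.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 5 or x.shape[1] != 2:
            raise ValueError(f"expected (B, 2, g, g, g), got {x.shape}")
        if x.data.min() < -1e-6 or x.data.max() > 1.0 + 1e-6:
            warnings.warn("input volumes are not normalized to [0, 1]",
                          stacklevel=2)
        B = x.shape[0]
        n = self.enc_cfg.final_filters
        streams = []
        attention: dict[str, AttentionStack] = {}
        for ch, (modality, encoder) in enumerate(
                [("smri", self.encoder_smri), ("pet", self.encoder_pet)]):
            maps = encoder(x[:, ch:ch + 1])          # (B, N, e, e, e)
            tokens = maps.reshape(B, n, -1)           # (B, N, d)
            if self.transformer is not None:
                tokens, stack = self.transformer(tokens)
                attention[modality] = stack
            streams.append(tokens.reshape(B, -1))
        fused = concat(streams, axis=1)
        return self.head(fused), attention

    def gates(self) -> list[float]:
        return [] if self.transformer is None else self.transformer.gates()


def assemble_model(enc_cfg: EncoderConfig | None = None,
                   tx_cfg: TransformerConfig | None = None,
                   fus_cfg: FusionConfig | None = None,
                   grid: int = 64, seed: int = 0) -> FusionNet:
    """Build a :class:`FusionNet`, deriving consistent defaults where omitted.

    The ablation in ``fus_cfg`` drives the transformer variant:
    ``typical_transformer`` switches to linear Q/K/V + positional embedding
    with an ungated residual.
    """
    enc_cfg = enc_cfg or EncoderConfig()
    fus_cfg = fus_cfg or FusionConfig()
    if tx_cfg is None:
        tx_cfg = TransformerConfig(n_tokens=enc_cfg.final_filters,
                                   token_dim=enc_cfg.token_dim(grid))
    if fus_cfg.ablation == "typical_transformer" and tx_cfg.variant != "typical":
        tx_cfg = TransformerConfig(**{**asdict(tx_cfg), "variant": "typical",
                                      "ffn_dim": tx_cfg.ffn_dim})
    return FusionNet(enc_cfg, tx_cfg, fus_cfg, grid, seed)


# -- losses and prediction -------------------------------------------------

def loss(pred: Prediction | np.ndarray, label: int | str) -> float:
    """Categorical cross-entropy of one prediction: -log p(true class).

    Zero probabilities are floored at the smallest positive float so the loss
    stays finite.
    """
    probs = pred.probs if isinstance(pred, Prediction) else np.asarray(pred)
    y = LABELS.index(label) if isinstance(label, str) else int(label)
    p = float(probs[y])
    return float(-np.log(max(p, float(np.finfo(np.float32).tiny))))


def batch_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch, from raw logits (training path)."""
    return cross_entropy_logits(logits, labels)


def subjects_to_array(subjects: list[Subject]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into (X (n, 2, g, g, g), y (n,)) arrays."""
    x = np.stack([np.stack([s.smri.data, s.pet.data]) for s in subjects])
    y = np.array([s.y for s in subjects], dtype=np.int64)
    return x.astype(np.float32), y


def predict_batch(model: FusionNet, x: np.ndarray, batch_size: int = 8,
                  record_attention: bool = False) -> list[Prediction]:
    """Eval-mode predictions for (n, 2, g, g, g) volumes, deterministic."""
    was_training = model.training
    model.eval()
    preds: list[Prediction] = []
    try:
        with no_grad():
            for start in range(0, x.shape[0], batch_size):
                xb = x[start:start + batch_size]
                logits, attention = model(xb)
                z = logits.data - logits.data.max(axis=1, keepdims=True)
                e = np.exp(z)
                probs = e / e.sum(axis=1, keepdims=True)
                for b in range(xb.shape[0]):
                    attn = {}
                    if record_attention:
                        attn = {m: stack.for_sample(b)
                                for m, stack in attention.items()}
                    preds.append(Prediction(
                        probs=probs[b],
                        label=LABELS[int(np.argmax(probs[b]))],
                        attention=attn))
    finally:
        model.train(was_training)
    return preds


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: FusionNet, path: str | Path) -> None:
    """Single-file checkpoint: all parameters/buffers + configs as JSON meta."""
    meta = {
        "enc_cfg": asdict(model.enc_cfg),
        "tx_cfg": asdict(model.tx_cfg),
        "fus_cfg": asdict(model.fus_cfg),
        "grid": model.grid,
        "seed": model.seed,
    }
    state = model.state_dict()
    np.savez_compressed(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> FusionNet:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    enc_cfg = EncoderConfig(**meta["enc_cfg"])
    tx_cfg = TransformerConfig(**meta["tx_cfg"])
    fus_cfg = FusionConfig(**meta["fus_cfg"])
    model = FusionNet(enc_cfg, tx_cfg, fus_cfg, meta["grid"], meta["seed"])
    model.load_state_dict(state)
    return model
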