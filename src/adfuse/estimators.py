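"""scikit-learn estimator interface to the fusion classifier.

:class:`FusionClassifier` wraps model assembly, training, and prediction in
the fit/predict idiom so the network composes with sklearn model selection
and pipelines.  ``X`` is an array of shape (n_subjects, 2, g, g, g) — channel
0 the sMRI volume, channel 1 the PET volume, both normalized to [0, 1] — or a
list of :class:`~adfuse.volumes.Subject`; ``y`` is 0 (CN) / 1 (AD).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .attention import TransformerConfig
from .encoder import EncoderConfig
from .model import FusionConfig, FusionNet, predict_batch, subjects_to_array
from .train import TrainConfig, train_model
from .volumes import Subject

__all__ = ["FusionClassifier"]


def _as_arrays(X, y=None):
    if len(X) and isinstance(X[0], Subject):
        xa, ya = subjects_to_array(list(X))
        return xa, (ya if y is None else np.asarray(y))
    xa = np.asarray(X, dtype=np.float32)
    if xa.ndim != 5 or xa.shape[1] != 2:
        raise ValueError(f"X must have shape (n, 2, g, g, g); got {xa.shape}")
    return xa, (None if y is None else np.asarray(y))


class FusionClassifier(ClassifierMixin, BaseEstimator):
    """Two-stream 3D CNN + gated Transformer classifier (AD vs CN).

    Parameters mirror the underlying configs; ``filters`` / ``final_filters``
    set the encoder, ``n_layers`` / ``n_heads`` the shared transformer, and
    ``ablation`` selects the full model or one of its reduced variants
    (``typical_transformer``, ``cnn_only``).  ``val_fraction`` > 0 holds out a
    stratified slice of the training data for best-epoch selection.

    Attributes (after fit): ``model_`` (the trained network), ``history_``
    (per-epoch training record), ``classes_``, ``gates_`` (final attention
    gate values per transformer block).
    """

    def __init__(self, grid: int = 64, filters: tuple[int, ...] = (15, 30, 60, 120, 160),
                 final_filters: int = 200, kernel: int = 3, n_layers: int = 2,
                 n_heads: int = 4, ffn_dim: int | None = None, mlp_hidden: int = 256,
                 dropout_p: float = 0.1, ablation: str = "full",
                 gate_lr_mult: float = 100.0, epochs: int = 60, batch_size: int = 11,
                 lr: float = 1e-4, lr_decay: float = 0.1, lr_step_epochs: int = 20,
                 val_fraction: float = 0.0, seed: int = 0):
        self.grid = grid
        self.filters = filters
        self.final_filters = final_filters
        self.kernel = kernel
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.mlp_hidden = mlp_hidden
        self.dropout_p = dropout_p
        self.ablation = ablation
        self.gate_lr_mult = gate_lr_mult
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_step_epochs = lr_step_epochs
        self.val_fraction = val_fraction
        self.seed = seed

    # -- config assembly ---------------------------------------------------

    def _configs(self):
        enc = EncoderConfig(n_blocks=len(self.filters), filters=tuple(self.filters),
                            kernel=self.kernel, final_filters=self.final_filters)
        tx = TransformerConfig(
            n_layers=self.n_layers, n_heads=self.n_heads,
            token_dim=enc.token_dim(self.grid), n_tokens=self.final_filters,
            ffn_dim=self.ffn_dim,
            variant="typical" if self.ablation == "typical_transformer" else "conv",
            gate_lr_mult=self.gate_lr_mult)
        fus = FusionConfig(mlp_hidden=self.mlp_hidden, dropout_p=self.dropout_p,
                           ablation=self.ablation)
        return enc, tx, fus

    def build_model(self, seed: int | None = None) -> FusionNet:
        enc, tx, fus = self._configs()
        return FusionNet(enc, tx, fus, self.grid, self.seed if seed is None else seed)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X, y = _as_arrays(X, y)
        if y is None:
            raise ValueError("y is required")
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        model = self.build_model()
        cfg = TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                          lr=self.lr, lr_decay=self.lr_decay,
                          lr_step_epochs=self.lr_step_epochs, seed=self.seed)
        x_val = y_val = None
        x_train, y_train = X, y
        if self.val_fraction > 0:
            rng = np.random.default_rng(self.seed)
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            order = rng.permutation(X.shape[0])
            val_idx, train_idx = order[:n_val], order[n_val:]
            x_train, y_train = X[train_idx], y[train_idx]
            x_val, y_val = X[val_idx], y[val_idx]
        self.history_ = train_model(model, x_train, y_train, x_val, y_val, cfg)
        self.model_ = model
        self.gates_ = model.gates()
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X, _ = _as_arrays(X)
        preds = predict_batch(self.model_, X, batch_size=self.batch_size)
        return np.stack([p.probs for p in preds])

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
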