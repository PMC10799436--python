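"""Model interpretability: attention rollout, feature decoding, clustering.

Pipeline: (1) average each layer's attention matrices over heads, add the
residual path as A = 0.5 W + 0.5 I, and multiply the augmented matrices
through the layers (attention rollout); (2) average the rollout matrix along
rows and columns to get one contribution weight per feature token and select
the highest-weight feature; (3) decode that feature back to image space with
a deconvolution network mirroring the CNN encoder (nearest-neighbour
upsampling + convolution, trained to reconstruct input volumes under MSE with
the encoder frozen); (4) keep the top percentile of the decoded salience map,
extract connected components, discard small ones, and report each surviving
cluster's peak coordinate, peak intensity, and voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import Adam, BatchNorm3d, Conv3d, Module
from ._tensor import Tensor, no_grad, upsample_nearest3d
from .attention import AttentionStack
from .encoder import Encoder3D, EncoderConfig, FeatureMapSet
from .volumes import Volume

__all__ = [
    "RolloutMap", "FeatureWeightVector", "DeconvConfig", "SalienceVolume",
    "Cluster", "ClusterReport", "residual_augment", "attention_rollout",
    "feature_weights", "average_feature_weights", "DeconvDecoder",
    "build_deconv", "train_deconv", "decode_feature", "salience_contrast",
    "threshold_and_cluster",
]

RESIDUAL_WEIGHT = 0.5  # weight of the identity path in the augmented matrix


def residual_augment(w: np.ndarray) -> np.ndarray:
    """A = 0.5 W + 0.5 I: fold the residual path into an attention matrix."""
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"attention matrix must be square, got {w.shape}")
    return RESIDUAL_WEIGHT * w + (1.0 - RESIDUAL_WEIGHT) * np.eye(w.shape[0])


@dataclass
class RolloutMap:
    """Final rollout matrix plus the per-layer augmented matrices."""

    matrix: np.ndarray
    per_layer: list[np.ndarray] = field(default_factory=list)


def attention_rollout(stack: AttentionStack | np.ndarray) -> RolloutMap:
    """Rollout over layers: A~(l_i) = A(l_i) @ A~(l_{i-1}), A~(l_1) = A(l_1).

    Input: an :class:`AttentionStack` for one sample, or an (L, H, N, N) /
    (L, N, N) array.  Head axes are averaged before augmentation.
    """
    if isinstance(stack, AttentionStack):
        mats = stack.for_sample(0) if stack.layers[0].ndim == 4 else \
            np.stack(stack.layers)
    else:
        mats = np.asarray(stack)
    if mats.ndim == 4:  # (L, H, N, N): average heads
        mats = mats.mean(axis=1)
    if mats.ndim != 3:
        raise ValueError(f"expected (L, H, N, N) or (L, N, N), got {mats.shape}")
    augmented = [residual_augment(w) for w in mats]
    rollout = augmented[0]
    per_layer = [rollout]
    for a in augmented[1:]:
        rollout = a @ rollout
        per_layer.append(rollout)
    return RolloutMap(matrix=rollout, per_layer=per_layer)


@dataclass
class FeatureWeightVector:
    """Per-feature contribution weights; argmax ties go to the lowest index."""

    weights: np.ndarray

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.weights))  # np.argmax returns the first max

    def __len__(self) -> int:
        return len(self.weights)


def feature_weights(rollout: RolloutMap | np.ndarray) -> FeatureWeightVector:
    """w_j = (mean of column j + mean of row j) / 2 of the rollout matrix."""
    a = rollout.matrix if isinstance(rollout, RolloutMap) else np.asarray(rollout)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"rollout matrix must be square, got {a.shape}")
    w = 0.5 * (a.mean(axis=0) + a.mean(axis=1))
    return FeatureWeightVector(weights=w)


def average_feature_weights(stacks: list[AttentionStack | np.ndarray],
                            correct: list[bool] | None = None,
                            correct_only: bool = False) -> FeatureWeightVector:
    """Per-sample rollout weights averaged over evaluation subjects.

    With ``correct_only`` only correctly classified subjects contribute.
    """
    vecs = []
    for i, stack in enumerate(stacks):
        if correct_only and correct is not None and not correct[i]:
            continue
        vecs.append(feature_weights(attention_rollout(stack)).weights)
    if not vecs:
        raise ValueError("no samples left to average (all filtered out)")
    return FeatureWeightVector(weights=np.mean(vecs, axis=0))


# ---------------------------------------------------------------------------
# Deconvolution decoder
# ---------------------------------------------------------------------------


@dataclass
class DeconvConfig:
    """Decoder training settings (reference protocol defaults)."""

    epochs: int = 3000
    batch_size: int = 20
    lr: float = 1e-4
    lr_decay: float = 0.5
    lr_step_epochs: int = 500
    l1: float = 0.0  # proximal L1 on decoder weights (sparse attribution)
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr * self.lr_decay ** ((epoch - 1) // self.lr_step_epochs)


class DeconvDecoder(Module):
    """Mirror image of the encoder: upsample (nearest) + conv per stage.

    Maps (B, final_filters, e, e, e) feature maps back to (B, 1, g, g, g)
    volumes.  By default the decoder is linear (convolutions and upsampling
    only), which makes the decoded volume an exact sum of per-channel
    contributions — decoding a single zero-masked feature then isolates that
    feature's additive contribution to the reconstruction, which is what the
    salience analysis interprets.  ``linear=False`` restores BN + ReLU hidden
    stages (a conventional trained deconvnet); the output convolution is
    always linear.
    """

    def __init__(self, enc_cfg: EncoderConfig, rng: np.random.Generator,
                 modality: str = "", linear: bool = True):
        super().__init__()
        self.enc_cfg = enc_cfg
        self.modality = modality
        self.linear = linear
        chans = [enc_cfg.final_filters] + list(reversed(enc_cfg.filters))
        self.stages: list[tuple[Conv3d, BatchNorm3d | None]] = []
        k = enc_cfg.kernel
        # first: undo the standalone conv (no resolution change)
        for i in range(len(chans) - 1):
            bias = not linear  # a linear decoder keeps strict additivity
            conv = Conv3d(chans[i], chans[i + 1], k, rng, padding="same", bias=bias)
            bn = BatchNorm3d(chans[i + 1]) if (enc_cfg.batch_norm and not linear) \
                else None
            setattr(self, f"conv{i}", conv)
            if bn is not None:
                setattr(self, f"bn{i}", bn)
            self.stages.append((conv, bn))
        self.out_conv = Conv3d(chans[-1], 1, k, rng, padding="same",
                               bias=not linear)

    def _stage(self, x: Tensor, conv: Conv3d, bn: BatchNorm3d | None) -> Tensor:
        x = conv(x)
        if bn is not None:
            x = bn(x)
        return x if self.linear else x.relu()

    def forward(self, feats: Tensor) -> Tensor:
        x = self._stage(feats, *self.stages[0])
        for conv, bn in self.stages[1:]:
            x = upsample_nearest3d(x, self.enc_cfg.pool)
            x = self._stage(x, conv, bn)
        x = upsample_nearest3d(x, self.enc_cfg.pool)
        return self.out_conv(x)


def build_deconv(enc_cfg: EncoderConfig, seed: int = 0, modality: str = "",
                 linear: bool = True) -> DeconvDecoder:
    return DeconvDecoder(enc_cfg, np.random.default_rng(seed), modality,
                         linear=linear)


def train_deconv(decoder: DeconvDecoder, encoder: Encoder3D,
                 volumes: np.ndarray, cfg: DeconvConfig | None = None,
                 feature_index: int | None = None,
                 mask: np.ndarray | None = None) -> list[float]:
    """Train the decoder to reconstruct ``volumes`` (n, g, g, g) under MSE.

    The encoder is frozen (eval mode, no gradients); only decoder parameters
    update.  Returns the per-epoch training MSE.

    With ``feature_index`` set, every channel except that one is zero-masked
    during training as well: the decoder then learns the best reconstruction
    of the image from the selected feature alone, so its output isolates what
    that feature encodes.  (A decoder trained on the full feature set splits
    reconstruction credit arbitrarily among correlated channels, which makes
    single-channel decodes uninformative about location.)

    ``mask`` (g, g, g) restricts the reconstruction loss to a region of
    interest — typically the brain support — so the decoder spends no
    capacity on the high-gradient support boundary.
    """
    cfg = cfg or DeconvConfig()
    rng = np.random.default_rng(cfg.seed)
    encoder.eval()
    decoder.train()
    x = np.asarray(volumes, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"expected (n, g, g, g) volumes, got {x.shape}")
    # precompute frozen encoder features once
    feats = []
    with no_grad():
        for start in range(0, x.shape[0], cfg.batch_size):
            out = encoder(Tensor(x[start:start + cfg.batch_size, None]))
            feats.append(out.data)
    feats = np.concatenate(feats, axis=0)
    if feature_index is not None:
        masked = np.zeros_like(feats)
        masked[:, feature_index] = feats[:, feature_index]
        feats = masked
    opt = Adam(decoder.parameters(), lr=cfg.lr)
    history = []
    n = x.shape[0]
    mask_t = None
    if mask is not None:
        m = np.asarray(mask, dtype=np.float32)
        mask_t = Tensor((m / max(m.mean(), 1e-12))[None, None])
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            recon = decoder(Tensor(feats[idx]))
            diff = recon - Tensor(x[idx][:, None])
            if mask_t is not None:
                diff = diff * mask_t
            mse = diff.pow(2.0).mean()
            opt.zero_grad()
            mse.backward()
            opt.step()
            if cfg.l1 > 0:
                # proximal step: soft-threshold weights toward sparse,
                # localized per-feature attribution fields
                thr = cfg.l1 * opt.lr
                for p in decoder.parameters():
                    p.data = np.sign(p.data) * np.maximum(
                        np.abs(p.data) - thr, 0.0)
            losses.append(float(mse.data))
        history.append(float(np.mean(losses)))
    decoder.eval()
    return history


@dataclass
class SalienceVolume:
    """Image-space salience decoded from one selected feature."""

    volume: Volume
    modality: str
    feature_index: int


def decode_feature(decoder: DeconvDecoder, features: FeatureMapSet, index: int,
                   affine: np.ndarray | None = None) -> SalienceVolume:
    """Decode a single feature map by zero-masking all other channels."""
    n = features.n_feat
    if not 0 <= index < n:
        raise IndexError(f"feature index {index} out of range [0, {n})")
    if features.modality and decoder.modality and \
            features.modality != decoder.modality:
        raise ValueError(
            f"modality mismatch: features are {features.modality!r} but the "
            f"decoder was trained for {decoder.modality!r}")
    masked = np.zeros_like(features.maps)
    masked[index] = features.maps[index]
    decoder.eval()
    with no_grad():
        out = decoder(Tensor(masked[None].astype(np.float32)))
    vol = Volume(out.data[0, 0], affine if affine is not None else np.eye(4))
    return SalienceVolume(volume=vol, modality=features.modality,
                          feature_index=index)


def salience_contrast(decoder: DeconvDecoder, encoder: Encoder3D,
                      volumes: np.ndarray, labels: np.ndarray, index: int,
                      positive_label: int = 1) -> Volume:
    """Group-contrast salience for one feature: mean decode(CN) - mean decode(AD).

    Decodes ``index`` for every subject and returns the difference of
    class-mean decoded volumes (label 0 minus ``positive_label``).  With a
    linear decoder this is the feature's contribution to the between-group
    intensity difference — the lesion/hypometabolism analogue the salience
    analysis is after — with the shared reconstruction background cancelled.
    """
    from .encoder import encode_volume

    labels = np.asarray(labels)
    sums = {0: None, 1: None}
    counts = {0: 0, 1: 0}
    for i in range(volumes.shape[0]):
        feats = encode_volume(encoder, volumes[i], decoder.modality)
        decoded = decode_feature(decoder, feats, index).volume.data
        cls = 1 if labels[i] == positive_label else 0
        sums[cls] = decoded if sums[cls] is None else sums[cls] + decoded
        counts[cls] += 1
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("salience contrast needs subjects of both classes")
    return Volume(sums[0] / counts[0] - sums[1] / counts[1])


# ---------------------------------------------------------------------------
# Cluster reporting
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    peak_ijk: tuple[int, int, int]
    peak_mm: np.ndarray
    peak_intensity: float
    n_voxels: int


@dataclass
class ClusterReport:
    """Surviving clusters sorted by size (descending) plus filter settings."""

    clusters: list[Cluster]
    top_pct: float
    min_size: int
    connectivity: int
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self):
        import pandas as pd
        rows = []
        for rank, c in enumerate(self.clusters, start=1):
            rows.append({
                "rank": rank,
                "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_voxel_ijk": "{} {} {}".format(*c.peak_ijk),
                "peak_intensity": c.peak_intensity,
                "voxels": c.n_voxels,
            })
        return pd.DataFrame(rows)


_STRUCTS = {6: ndimage.generate_binary_structure(3, 1),
            18: ndimage.generate_binary_structure(3, 2),
            26: ndimage.generate_binary_structure(3, 3)}


def threshold_and_cluster(sal: SalienceVolume | Volume | np.ndarray,
                          top_pct: float = 1.0, min_size: int = 100,
                          connectivity: int = 26) -> ClusterReport:
    """Keep the top ``top_pct`` percent of voxels, then filter components.

    Voxels at or above the (100 - top_pct) percentile are retained; connected
    components (at the given connectivity) with size strictly greater than
    ``min_size`` are reported with their peak voxel, peak intensity (raw
    decoded value), and voxel count, sorted largest first.
    """
    if isinstance(sal, SalienceVolume):
        vol = sal.volume
    elif isinstance(sal, Volume):
        vol = sal
    else:
        vol = Volume(np.asarray(sal))
    data = np.asarray(vol.data, dtype=np.float64)
    if data.max() == data.min():
        raise ValueError("salience map is constant; percentile threshold "
                         "is degenerate")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    cutoff = float(np.percentile(data, 100.0 - top_pct))
    mask = data >= cutoff
    labeled, n_comp = ndimage.label(mask, structure=_STRUCTS[connectivity])
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        voxels = np.flatnonzero(labeled == comp)
        size = voxels.size
        if size <= min_size:
            continue
        coords = np.unravel_index(voxels, data.shape)
        vals = data[coords]
        peak_local = int(np.argmax(vals))
        peak_ijk = tuple(int(c[peak_local]) for c in coords)
        clusters.append(Cluster(
            peak_ijk=peak_ijk,
            peak_mm=vol.voxel_to_mm(peak_ijk),
            peak_intensity=float(vals[peak_local]),
            n_voxels=int(size)))
    clusters.sort(key=lambda c: c.n_voxels, reverse=True)
    return ClusterReport(clusters=clusters, top_pct=top_pct, min_size=min_size,
                         connectivity=connectivity, threshold=cutoff)
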