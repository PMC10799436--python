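"""Per-modality 3D convolutional feature extractor.

Five conv + max-pool blocks followed by one standalone convolution turn a
64^3 single-channel volume into 200 feature maps of spatial extent 2x2x2.
Each convolution is followed by batch normalization and ReLU; pooling halves
every spatial dimension, so the final extent is ``grid / 2**n_blocks``.

The sMRI and PET encoders share this architecture but never share parameters;
construct one encoder per modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import BatchNorm3d, Conv3d, MaxPool3d, Module
from ._tensor import Tensor

__all__ = ["EncoderConfig", "FeatureMapSet", "ConvBlock", "Encoder3D",
           "encode_volume"]


@dataclass
class EncoderConfig:
    """Geometry of the convolutional feature extractor.

    ``filters`` are the output channels of the stacked conv+pool blocks;
    ``final_filters`` is the channel count of the last, standalone convolution
    whose output maps become the attention tokens.  With the defaults, a 64^3
    input yields 200 maps of 2x2x2 (token dim 8 after flattening).
    """

    n_blocks: int = 5
    filters: tuple[int, ...] = (15, 30, 60, 120, 160)
    kernel: int = 3
    conv_stride: int = 1
    pool: int = 2
    final_filters: int = 200
    batch_norm: bool = True

    def __post_init__(self):
        self.filters = tuple(self.filters)
        if len(self.filters) != self.n_blocks:
            raise ValueError(
                f"filters has {len(self.filters)} entries for {self.n_blocks} blocks")

    def output_extent(self, grid: int) -> int:
        """Spatial edge length of the final feature maps for a cubic input."""
        e = grid
        sizes = [e]
        for _ in range(self.n_blocks):
            e = e // self.conv_stride
            if e % self.pool:
                raise ValueError(
                    f"input extent {grid} incompatible with config; per-layer "
                    f"extents so far: {sizes}")
            e //= self.pool
            sizes.append(e)
        if e < 1:
            raise ValueError(f"input extent {grid} collapses below 1: {sizes}")
        return e

    @property
    def token_count(self) -> int:
        return self.final_filters

    def token_dim(self, grid: int) -> int:
        return self.output_extent(grid) ** 3


@dataclass
class FeatureMapSet:
    """Encoder output: ``maps`` of shape (n_feat, dx, dy, dz) for one subject."""

    maps: np.ndarray
    modality: str = ""

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 4:
            raise ValueError(f"expected (n_feat, dx, dy, dz), got {self.maps.shape}")

    @property
    def n_feat(self) -> int:
        return self.maps.shape[0]

    def tokens(self) -> np.ndarray:
        """Flatten each map's voxels into a token row: (n_feat, dx*dy*dz)."""
        return self.maps.reshape(self.n_feat, -1)


class ConvBlock(Module):
    """conv -> batch norm -> ReLU, optionally followed by max pooling."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pool: int | None = 2, batch_norm: bool = True):
        super().__init__()
        self.conv = Conv3d(in_ch, out_ch, kernel, rng, stride=stride, padding="same")
        self.bn = BatchNorm3d(out_ch) if batch_norm else None
        self.pooling = MaxPool3d(pool) if pool else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        x = x.relu()
        if self.pooling is not None:
            x = self.pooling(x)
        return x


class Encoder3D(Module):
    """Stack of conv+pool blocks plus a final standalone convolution.

    Input: (B, 1, g, g, g) volumes in [0, 1].
    Output: (B, final_filters, e, e, e) non-negative feature maps, where
    ``e = cfg.output_extent(g)``.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        in_ch = 1
        self.blocks: list[ConvBlock] = []
        for i, out_ch in enumerate(cfg.filters):
            block = ConvBlock(in_ch, out_ch, cfg.kernel, rng, stride=cfg.conv_stride,
                              pool=cfg.pool, batch_norm=cfg.batch_norm)
            setattr(self, f"block{i}", block)
            self.blocks.append(block)
            in_ch = out_ch
        # last layer: standalone conv (no pooling), still BN + ReLU
        self.final = ConvBlock(in_ch, cfg.final_filters, cfg.kernel, rng,
                               stride=1, pool=None, batch_norm=cfg.batch_norm)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (B, 1, g, g, g) input, got {x.shape}")
        self.cfg.output_extent(x.shape[2])  # raises with per-layer sizes if bad
        for block in self.blocks:
            x = block(x)
        return self.final(x)


def encode_volume(encoder: Encoder3D, vol_data: np.ndarray, modality: str = ""
                  ) -> FeatureMapSet:
    """Run one volume through a (trained) encoder in eval mode."""
    from ._tensor import no_grad

    was_training = encoder.training
    encoder.eval()
    try:
        with no_grad():
            x = Tensor(np.asarray(vol_data, dtype=np.float32)[None, None])
            out = encoder(x)
    finally:
        encoder.train(was_training)
    return FeatureMapSet(out.data[0], modality=modality)
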