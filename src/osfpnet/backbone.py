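"""Feature-extraction backbone: VGG16-style convolutional blocks.

The backbone maps a single-view image of arbitrary size to ``k`` feature
maps at 1/16 resolution.  It is the VGG16 convolutional stage — five blocks
of 3x3/stride-1/pad-1 convolutions with ReLU, each block followed by a 2x2
stride-2 max pool — except that, in the reference configuration, the pool
after the last block is omitted so the final feature map keeps as much
spatial extent as possible before object-specific pooling.

Because every convolution preserves spatial dims and every pool halves them
(floor), an H x W input yields a ``floor(H/16) x floor(W/16)`` map with the
default four pools.  The downstream 3-level pooling needs a map of at least
3x3, hence the 48-px minimum input side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["BackboneConfig", "FeatureMap", "Backbone", "build_backbone", "extract"]

#: channel mean/std used by ILSVRC-pretrained checkpoints (RGB order)
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)


@dataclass(frozen=True)
class BackboneConfig:
    n_blocks: int = 5
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    pool_after_last_block: bool = False
    pretrained: bool = False
    pretrained_weights: str | None = None
    width_scale: float = 1.0
    in_channels: int = 3

    def __post_init__(self):
        if len(self.convs_per_block) != self.n_blocks or len(self.channels) != self.n_blocks:
            raise ValueError(
                f"convs_per_block and channels must each have n_blocks={self.n_blocks} "
                f"entries, got {len(self.convs_per_block)} and {len(self.channels)}"
            )
        if self.width_scale <= 0:
            raise ValueError(f"width_scale must be positive, got {self.width_scale}")
        if self.pretrained and self.width_scale != 1.0:
            raise ValueError(
                "pretrained weights require width_scale=1.0 (checkpoint shapes are fixed); "
                f"got width_scale={self.width_scale}"
            )
        if self.pretrained and self.in_channels != 3:
            raise ValueError("pretrained weights require in_channels=3 (RGB replication)")

    @property
    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(max(1, round(c * self.width_scale)) for c in self.channels)

    @property
    def out_channels(self) -> int:
        """k: channel count of the final feature maps."""
        return self.scaled_channels[-1]

    @property
    def n_pools(self) -> int:
        return self.n_blocks if self.pool_after_last_block else self.n_blocks - 1

    @property
    def min_input(self) -> int:
        """Smallest input side giving a >=3x3 final map (3-level pooling)."""
        return 3 * 2 ** self.n_pools

    def spatial_out(self, extent: int) -> int:
        """Floor chain of ``extent`` through the stride-2 pools."""
        return extent // 2 ** self.n_pools

    @property
    def n_params(self) -> int:
        """Weight + bias count of all convolution layers."""
        total, c_in = 0, self.in_channels
        for n_conv, c_out in zip(self.convs_per_block, self.scaled_channels):
            for _ in range(n_conv):
                total += 9 * c_in * c_out + c_out
                c_in = c_out
        return total

    @classmethod
    def tiny(cls, in_channels: int = 1) -> "BackboneConfig":
        """Desk-scale variant (width_scale=0.125, k=64) for CPU runs."""
        return cls(width_scale=0.125, in_channels=in_channels)


@dataclass
class FeatureMap:
    """k feature maps of one view: values laid out (k, h, w)."""

    values: np.ndarray

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def h(self) -> int:
        return self.values.shape[1]

    @property
    def w(self) -> int:
        return self.values.shape[2]


class Backbone:
    """Stack of conv/ReLU/pool layers built from a :class:`BackboneConfig`."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in = cfg.in_channels
        for b, (n_conv, c_out) in enumerate(zip(cfg.convs_per_block, cfg.scaled_channels)):
            for _ in range(n_conv):
                self.layers.append(nn.Conv3x3(c_in, c_out, rng, dtype))
                self.layers.append(nn.ReLU())
                c_in = c_out
            if b < cfg.n_blocks - 1 or cfg.pool_after_last_block:
                self.layers.append(nn.MaxPool2())
        if cfg.pretrained:
            self._load_pretrained(cfg.pretrained_weights)

    def _load_pretrained(self, path: str | None):
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                "pretrained=True needs an .npz checkpoint of the 13 VGG16 conv layers "
                "(arrays conv0_w, conv0_b, ..., conv12_w, conv12_b, torch layout "
                "(out, in, 3, 3)); export one offline and point pretrained_weights at it"
                + (f"; got missing path {path!r}" if path else "")
            )
        data = np.load(path)
        convs = [l for l in self.layers if isinstance(l, nn.Conv3x3)]
        for i, conv in enumerate(convs):
            w, b = data[f"conv{i}_w"], data[f"conv{i}_b"]
            if w.shape != conv.w.shape:
                raise ValueError(
                    f"checkpoint conv{i} shape {w.shape} != model {conv.w.shape}"
                )
            conv.w[...] = w.astype(self.dtype)
            conv.b[...] = b.astype(self.dtype)

    # -- parameters ---------------------------------------------------------
    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(w.size for w, _ in self.params())

    @property
    def out_channels(self) -> int:
        return self.cfg.out_channels

    @property
    def min_input(self) -> int:
        return self.cfg.min_input

    # -- forward/backward ---------------------------------------------------
    def prepare(self, image: np.ndarray) -> np.ndarray:
        """Normalise a raw image to the (C, H, W) float tensor the net expects.

        8-bit intensities are scaled to [0, 1]; a 2-D grayscale image is
        replicated across ``in_channels``; pretrained configurations apply
        the checkpoint's canonical per-channel normalisation.
        """
        x = np.asarray(image)
        if x.ndim == 2:
            x = x[None].repeat(self.cfg.in_channels, axis=0)
        elif x.ndim != 3 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected (H, W) or ({self.cfg.in_channels}, H, W) image, got {x.shape}"
            )
        x = x.astype(self.dtype)
        if np.issubdtype(np.asarray(image).dtype, np.integer):
            x = x / np.asarray(255.0, dtype=self.dtype)
        if self.cfg.pretrained:
            x = (x - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]
            x = x.astype(self.dtype)
        return x

    def _check_size(self, h: int, w: int):
        m = self.min_input
        if h < m or w < m:
            raise ValueError(
                f"input {h}x{w} smaller than the minimum accepted size {m}x{m} "
                f"(needed for a >=3x3 final feature map)"
            )

    def forward(self, x: np.ndarray):
        """Run prepared input through all layers; returns (feature map, caches)."""
        self._check_size(x.shape[1], x.shape[2])
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dout: np.ndarray, caches):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dout = l.backward(dout, c)
        return dout


def build_backbone(cfg: BackboneConfig, seed: int = 0, dtype=np.float32) -> Backbone:
    """Construct a feature-extraction backbone (random He init unless pretrained)."""
    return Backbone(cfg, seed=seed, dtype=dtype)


def extract(fe: Backbone, image: np.ndarray) -> FeatureMap:
    """Inference-mode feature extraction of one arbitrary-size image."""
    x = fe.prepare(image)
    fmap, _ = fe.forward(x)
    return FeatureMap(fmap)
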