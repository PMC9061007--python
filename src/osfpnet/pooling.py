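"""Object-specific pooling: spatial pyramid pooling (SPP) and multilevel
strip pooling (MSP).

Both modules map a feature stack of arbitrary spatial extent to a vector of
fixed length.  A pooling spec is a list of levels; level ``(a, b)``
partitions the map into an adaptive grid of ``a`` bins along the height and
``b`` bins along the width, and reduces each bin (over its cells, per
channel) with a ``max`` or ``average`` operator.

* SPP levels are square grids ``(a, a)`` — suited to near-square transverse
  plaque ROIs.  The default 3-level spec (1x1, 2x2, 3x3) yields 14 bins.
* MSP levels are horizontal strips ``(a, 1)`` spanning the full width —
  suited to elongated longitudinal ROIs, where each strip aggregates
  long-range horizontal context.  The default (1x1, 2x1, 3x1) yields
  6 strips.

With ``k`` channels the descriptor length is ``k * sum(a_n * b_n)``
independently of the input size: 14k for the default SPP and 6k for the
default MSP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoolingSpec",
    "FixedLengthDescriptor",
    "adaptive_bin_edges",
    "pool",
    "pool_backward",
]


def adaptive_bin_edges(extent: int, n_bins: int) -> list[tuple[int, int]]:
    """Adaptive partition of ``range(extent)`` into ``n_bins`` index ranges.

    Bin ``i`` covers the half-open range
    ``[floor(i * extent / n), ceil((i + 1) * extent / n))``.  The union of
    the bins always covers every index; when ``extent`` is not a multiple of
    ``n_bins`` adjacent bins may overlap by at most one cell.  This is the
    standard adaptive-pooling boundary convention.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if n_bins > extent:
        raise ValueError(
            f"cannot split extent {extent} into {n_bins} non-empty bins"
        )
    return [
        (math.floor(i * extent / n_bins), math.ceil((i + 1) * extent / n_bins))
        for i in range(n_bins)
    ]


@dataclass(frozen=True)
class PoolingSpec:
    """Level structure of one object-specific pooling module.

    ``levels`` is a sequence of ``(a, b)`` grid shapes.  SPP requires square
    levels (b == a); MSP requires strip levels (b == 1).
    """

    kind: str  # "SPP" | "MSP"
    levels: tuple[tuple[int, int], ...]
    operator: str = "max"  # "max" | "average"

    def __post_init__(self):
        if self.kind not in ("SPP", "MSP"):
            raise ValueError(f"kind must be 'SPP' or 'MSP', got {self.kind!r}")
        if self.operator not in ("max", "average"):
            raise ValueError(f"operator must be 'max' or 'average', got {self.operator!r}")
        if not self.levels:
            raise ValueError("at least one pooling level is required")
        lv = tuple((int(a), int(b)) for a, b in self.levels)
        object.__setattr__(self, "levels", lv)
        for a, b in lv:
            if a < 1 or b < 1:
                raise ValueError(f"level shapes must be positive, got {(a, b)}")
            if self.kind == "SPP" and b != a:
                raise ValueError(f"SPP levels must be square, got {(a, b)}")
            if self.kind == "MSP" and b != 1:
                raise ValueError(f"MSP levels must be strips (a, 1), got {(a, b)}")

    @property
    def total_units(self) -> int:
        """Total pooled bins/strips per channel: sum of a_n * b_n."""
        return sum(a * b for a, b in self.levels)

    @property
    def min_map_size(self) -> tuple[int, int]:
        """Smallest (h, w) feature map this spec can pool."""
        return (max(a for a, _ in self.levels), max(b for _, b in self.levels))

    @classmethod
    def spp_default(cls, operator: str = "max") -> "PoolingSpec":
        """3-level pyramid 1x1, 2x2, 3x3 — 14 bins per channel."""
        return cls("SPP", ((1, 1), (2, 2), (3, 3)), operator)

    @classmethod
    def msp_default(cls, operator: str = "average") -> "PoolingSpec":
        """3-level strips 1x1, 2x1, 3x1 — 6 strips per channel."""
        return cls("MSP", ((1, 1), (2, 1), (3, 1)), operator)


@dataclass
class FixedLengthDescriptor:
    """Fixed-length pooled feature vector from one network path."""

    values: np.ndarray
    source_path: int | None = None


def _as_array(feature_map) -> np.ndarray:
    arr = getattr(feature_map, "values", feature_map)
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"feature map must be (k, h, w), got shape {arr.shape}")
    return arr


def pool(feature_map, spec: PoolingSpec, source_path: int | None = None):
    """Pool a (k, h, w) feature stack to a length ``k * total_units`` vector.

    Output layout: levels in listed order; within a level the channels are
    contiguous, each channel contributing its bins in row-major grid order.
    """
    desc, _ = _pool_with_cache(_as_array(feature_map), spec)
    return FixedLengthDescriptor(desc, source_path)


def _pool_with_cache(arr: np.ndarray, spec: PoolingSpec):
    k, h, w = arr.shape
    need_h, need_w = spec.min_map_size
    if h < need_h or w < need_w:
        raise ValueError(
            f"feature map {h}x{w} too small for {spec.kind} levels {spec.levels}: "
            f"needs at least {need_h}x{need_w}"
        )
    blocks, cache = [], []
    for a, b in spec.levels:
        rows = adaptive_bin_edges(h, a)
        cols = adaptive_bin_edges(w, b)
        vals = np.empty((k, a, b), dtype=arr.dtype)
        bins = []
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                patch = arr[:, r0:r1, c0:c1].reshape(k, -1)
                if spec.operator == "max":
                    idx = patch.argmax(axis=1)
                    vals[:, i, j] = np.take_along_axis(patch, idx[:, None], 1)[:, 0]
                    bins.append((r0, r1, c0, c1, idx))
                else:
                    vals[:, i, j] = patch.mean(axis=1)
                    bins.append((r0, r1, c0, c1, None))
        blocks.append(vals.reshape(k, a * b).ravel())
        cache.append(bins)
    return np.concatenate(blocks), (arr.shape, cache)


def pool_backward(dvec: np.ndarray, spec: PoolingSpec, cache) -> np.ndarray:
    """Gradient of :func:`pool` with respect to the feature map."""
    (k, h, w), level_bins = cache
    dmap = np.zeros((k, h, w), dtype=dvec.dtype)
    off = 0
    chan = np.arange(k)
    for (a, b), bins in zip(spec.levels, level_bins):
        units = a * b
        dlvl = dvec[off: off + k * units].reshape(k, a, b)
        off += k * units
        for u, (r0, r1, c0, c1, idx) in enumerate(bins):
            i, j = divmod(u, b)
            g = dlvl[:, i, j]
            if idx is not None:  # max: route to the argmax cell per channel
                bw = c1 - c0
                ri, ci = np.divmod(idx, bw)
                dmap[chan, r0 + ri, c0 + ci] += g
            else:  # average: spread uniformly over the bin
                area = (r1 - r0) * (c1 - c0)
                dmap[:, r0:r1, c0:c1] += (g / area)[:, None, None]
    return dmap
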