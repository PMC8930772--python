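"""Per-pixel prediction maps produced by the segmentation network.

The network makes three pixel-wise predictions: a seed score in [0, 1],
a positive scalar bandwidth sigma, and a two-component spatial offset.
The spatial embedding of pixel i is e_i = x_i + o_i, where x_i is the
pixel's (row, col) coordinate divided by ``coord_scale``.  By default
``coord_scale`` is the larger image dimension, but it can be pinned so
that maps computed on training crops and on full-size fields share one
coordinate unit (bandwidths are expressed in that unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PredictionMaps"]


@dataclass
class PredictionMaps:
    seed: np.ndarray  # (H, W) in [0, 1]
    bandwidth: np.ndarray  # (H, W), > 0
    offsets: np.ndarray  # (2, H, W): row and col offset components
    coord_scale: float = field(default=0.0)  # pixels per embedding unit; 0 -> max(H, W)

    def __post_init__(self) -> None:
        self.seed = np.asarray(self.seed, dtype=np.float64)
        self.bandwidth = np.asarray(self.bandwidth, dtype=np.float64)
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if self.seed.ndim != 2:
            raise ValueError("seed map must be 2D")
        if self.bandwidth.shape != self.seed.shape:
            raise ValueError("bandwidth map shape differs from seed map")
        if self.offsets.shape != (2,) + self.seed.shape:
            raise ValueError("offsets must have shape (2, H, W)")
        if self.seed.min() < 0 or self.seed.max() > 1:
            raise ValueError("seed scores must lie in [0, 1]")
        if self.bandwidth.min() <= 0:
            raise ValueError("bandwidths must be positive")
        if not self.coord_scale:
            self.coord_scale = float(max(self.seed.shape))
        if self.coord_scale <= 0:
            raise ValueError("coord_scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.seed.shape

    def pixel_coords(self) -> np.ndarray:
        """Normalized pixel coordinate grid, shape (2, H, W)."""
        h, w = self.shape
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        return np.stack([rr, cc]).astype(np.float64) / self.coord_scale

    def embeddings(self) -> np.ndarray:
        """Spatial embeddings e = x + o, shape (2, H, W)."""
        return self.pixel_coords() + self.offsets
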