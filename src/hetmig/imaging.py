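"""Multi-frame grayscale image stacks for the nucleus tracker.

Brightness is rescaled to [0, 100]; one pixel is ``pixel_size`` μm (5 μm for
the emulated microscope), frames ``frame_interval`` minutes apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Frames of shape (n_frames, height, width), brightness in [0, 100]."""

    frames: np.ndarray
    pixel_size: float = 5.0  # μm per pixel
    frame_interval: float = 2.0  # min

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frames.min() < 0 or self.frames.max() > 100:
            raise ValueError("brightness must lie within [0, 100]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         photometric="minisblack")

    @classmethod
    def from_tiff(
        cls, path: str | Path, pixel_size: float = 5.0, frame_interval: float = 2.0
    ) -> "ImageStack":
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, pixel_size, frame_interval)
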