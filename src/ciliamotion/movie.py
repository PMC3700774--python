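"""In-memory time-lapse movie container."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError

__all__ = ["MovieStack"]


@dataclass
class MovieStack:
    """Ordered stack of 2-D grayscale frames with acquisition metadata.

    ``fps`` always comes from the user or the sidecar file, never from
    TIFF tags.  ``pixel_size_um`` is metadata only; all geometry in the
    package is in pixels.
    """

    frames: np.ndarray  # (T, H, W), non-negative
    fps: float
    pixel_size_um: Optional[float] = None
    source: str = "synthetic"
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ConfigError(
                f"frames must be a (T, H, W) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ConfigError("movie must contain at least one frame")
        if not self.fps > 0:
            raise ConfigError("fps must be > 0")
        if np.any(np.asarray(self.frames[0], dtype=float) < 0):
            # only the first frame is checked eagerly; writers re-validate
            raise ConfigError("frame intensities must be non-negative")
        if self.bit_depth is None and self.frames.dtype == np.uint8:
            self.bit_depth = 8
        elif self.bit_depth is None and self.frames.dtype == np.uint16:
            self.bit_depth = 16

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple:
        return tuple(self.frames.shape[1:])

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) / self.fps

    @property
    def usable_for_motion(self) -> bool:
        """Motion analysis needs more than one frame."""
        return self.n_frames > 1
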