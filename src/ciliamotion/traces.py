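"""Tip-angle time series.

Angles are measured in the image plane, in degrees: 0° is wall-parallel
pointing downstream (+x) and 90° is perpendicular to the tubule wall,
pointing into the lumen.  Frames are 0-based; frame ``k`` is stamped
``k / fps`` seconds (half-open interval convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["AngleTrace"]

#: quality flag values
QUALITY_OK = "ok"
QUALITY_LOW_SIGNAL = "low_signal"


@dataclass
class AngleTrace:
    """Uniformly sampled in-plane tip angle of one cilium.

    Parameters
    ----------
    times
        Frame timestamps in seconds, strictly increasing and uniformly
        spaced (to within 1 ns).
    angles
        Tip angle per frame, degrees, within [0, 180].
    low_signal
        Boolean mask of frames whose angle was interpolated because no
        bin cleared the signal threshold; ``False`` everywhere for
        ground-truth traces.
    """

    times: np.ndarray
    angles: np.ndarray
    low_signal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.low_signal is None:
            self.low_signal = np.zeros(self.times.shape, dtype=bool)
        self.low_signal = np.asarray(self.low_signal, dtype=bool)
        if self.times.ndim != 1 or self.times.shape != self.angles.shape:
            raise ConfigError("times and angles must be 1-D arrays of equal length")
        if self.low_signal.shape != self.times.shape:
            raise ConfigError("low_signal mask length must match times")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ConfigError("times must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ConfigError("times must be uniformly spaced to within 1e-9 s")
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise ConfigError("angles must lie within [0, 180] degrees")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def fps(self) -> float:
        """Sampling rate inferred from the (uniform) timestamps."""
        if self.times.size < 2:
            raise ConfigError("fps undefined for a single-frame trace")
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Record length in seconds (frame count / fps)."""
        return self.n_frames / self.fps

    @property
    def ok(self) -> np.ndarray:
        """Mask of quality-ok frames."""
        return ~self.low_signal

    @property
    def quality(self) -> np.ndarray:
        """Per-frame string flags (``ok`` / ``low_signal``)."""
        return np.where(self.low_signal, QUALITY_LOW_SIGNAL, QUALITY_OK)
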