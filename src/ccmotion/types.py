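"""Core kinematic container shared by every module.

All motion in this package is one-dimensional: a stylus, handle or cursor
moving left-right along a track. A :class:`Trajectory` holds uniformly
sampled position (cm), velocity (cm/s) and acceleration (cm/s^2) channels
of equal length, plus the sample rate and the absolute time of the first
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Uniformly sampled 1-D kinematic trace.

    Parameters
    ----------
    sample_rate : float
        Samples per second (Hz).
    position, velocity, acceleration : ndarray
        Equal-length channels in cm, cm/s and cm/s^2.
    t0 : float
        Time of the first sample, in seconds.
    """

    sample_rate: float
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        n = len(self.position)
        if len(self.velocity) != n or len(self.acceleration) != n:
            raise ValueError("position, velocity and acceleration must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.position)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Length of the sampled support in seconds (n / rate)."""
        return len(self) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sample_rate

    def index_range(self, t_start: float, t_end: float) -> tuple[int, int]:
        """Half-open sample index range covering times in [t_start, t_end)."""
        eps = 1e-9
        i0 = int(np.ceil((t_start - self.t0) * self.sample_rate - eps))
        i1 = int(np.ceil((t_end - self.t0) * self.sample_rate - eps))
        return max(i0, 0), min(max(i1, 0), len(self))

    def copy(self) -> "Trajectory":
        return replace(
            self,
            position=self.position.copy(),
            velocity=self.velocity.copy(),
            acceleration=self.acceleration.copy(),
        )
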