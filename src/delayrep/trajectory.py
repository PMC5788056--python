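"""Uniformly sampled 2D hand/target/paddle position time series.

The whole pipeline works in one currency: position in centimetres on a
frontal (x) / sagittal (y) plane, sampled at a fixed rate in Hz, with
time in seconds.  Forward (away from the body) is positive y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]

#: tolerated jitter of successive sample intervals around 1/rate, seconds
_DT_TOL = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled planar trajectory.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, uniform to within
        1 ns per step.
    x, y : array of float
        Frontal / sagittal position in cm.
    rate : float
        Sampling frequency in Hz.  Consistency with ``t`` is enforced.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        for name in ("t", "x", "y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if not (self.t.ndim == self.x.ndim == self.y.ndim == 1):
            raise ValueError("t, x, y must be one-dimensional")
        n = len(self.t)
        if n < 2:
            raise ValueError("a trajectory needs at least two samples")
        if len(self.x) != n or len(self.y) != n:
            raise ValueError(
                f"length mismatch: t={n}, x={len(self.x)}, y={len(self.y)}"
            )
        if not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
        ):
            raise ValueError("trajectory contains non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.max(np.abs(dt - 1.0 / self.rate)) > _DT_TOL:
            raise ValueError(
                "non-uniform sampling: successive dt deviate from 1/rate "
                f"by more than {_DT_TOL} s"
            )

    # -- convenience -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) samples."""
        return np.column_stack([self.x, self.y])

    def with_xy(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        """Same time base, new coordinates."""
        return Trajectory(t=self.t.copy(), x=np.asarray(x, float),
                          y=np.asarray(y, float), rate=self.rate)

    def copy(self) -> "Trajectory":
        return Trajectory(self.t.copy(), self.x.copy(), self.y.copy(), self.rate)

    @classmethod
    def from_samples(cls, x: np.ndarray, y: np.ndarray, rate: float,
                     t0: float = 0.0) -> "Trajectory":
        """Build a trajectory from coordinate arrays and a sampling rate."""
        x = np.asarray(x, float)
        t = t0 + np.arange(len(x)) / rate
        return cls(t=t, x=x, y=np.asarray(y, float), rate=rate)
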