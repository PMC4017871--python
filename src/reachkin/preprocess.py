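"""Trajectory smoothing and velocity estimation.

The acquisition chain low-pass filters every marker coordinate with a
five-point triangular smooth, i.e. convolution with the normalised
triangular kernel (1, 2, 3, 2, 1)/9.  At the record edges the kernel is
renormalised over the available samples, which keeps the DC gain at
exactly 1 everywhere.  Velocities are central differences scaled by the
sampling frequency; the hand's tangential (resultant 3-D) speed is the
signal on which movement units are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScalarSeries",
    "TRIANGULAR_KERNEL",
    "triangular_smooth",
    "differentiate",
    "tangential_speed",
]

TRIANGULAR_KERNEL = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0


@dataclass
class ScalarSeries:
    """A time-ordered scalar signal with its sampling rate and unit."""

    values: np.ndarray
    fs: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.isfinite(self.values).all():
            raise ValueError("ScalarSeries contains non-finite values")


def triangular_smooth(x: np.ndarray, passes: int = 1) -> np.ndarray:
    """Apply the five-point triangular smooth along axis 0.

    Works on 1-D scalar signals and (n, 3) trajectories alike.  Edge
    samples are smoothed with the kernel renormalised over the in-range
    taps, preserving constants exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError(f"triangular smooth needs >= 5 samples, got {n}")
    if passes < 0:
        raise ValueError("passes must be >= 0")
    out = x
    ones = np.ones(n)
    for _ in range(passes):
        if out.ndim == 1:
            num = np.convolve(out, TRIANGULAR_KERNEL, mode="same")
        else:
            num = np.stack(
                [np.convolve(out[:, j], TRIANGULAR_KERNEL, mode="same") for j in range(out.shape[1])],
                axis=1,
            )
        den = np.convolve(ones, TRIANGULAR_KERNEL, mode="same")
        out = num / (den if out.ndim == 1 else den[:, None])
    return out


def differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    """First time derivative along axis 0: central differences at the
    interior, one-sided at the ends, scaled to units/second."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError(f"differentiate needs >= 3 samples, got {x.shape[0]}")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    return np.gradient(x, 1.0 / fs, axis=0)


def tangential_speed(
    trajectory: np.ndarray,
    fs: float,
    presmooth_passes: int = 1,
    speed_passes: int = 0,
) -> np.ndarray:
    """Resultant 3-D speed (mm/s) of a marker trajectory.

    The trajectory is smoothed coordinate-wise (``presmooth_passes``
    applications of the triangular filter) before differentiation; the
    resulting speed signal can optionally be smoothed again
    (``speed_passes``), which event detection and movement-unit counting
    use to suppress differentiation-amplified marker noise.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 3:
        raise ValueError("trajectory must have shape (n, 3)")
    if presmooth_passes:
        traj = triangular_smooth(traj, passes=presmooth_passes)
    vel = differentiate(traj, fs)
    speed = np.linalg.norm(vel, axis=1)
    if speed_passes:
        speed = triangular_smooth(speed, passes=speed_passes)
    return speed
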