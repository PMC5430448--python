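"""Sample drift as a point mass with drag in a flowing medium.

The per-axis drift velocity follows an Ornstein-Uhlenbeck process around the
configured mean velocity: random forces alone would let the velocity random
walk, while the drag term pulls it back toward the mean, so the trajectory
wanders locally but keeps its mean velocity on large scales.  Discretization
is Euler-Maruyama with one step per frame,

    v[t+1] = v[t] - k (v[t] - v_mean) dt + sigma_v sqrt(dt) xi,

with ``xi`` standard normal; positions are the cumulative sum of ``v dt``
with offset zero at the first frame.  The stationary velocity variance is
``sigma_v^2 / (2 k)`` per axis.

Drift is applied to molecule positions (the sample moves under a fixed
optical system), so the defocus-dependent PSF shape stays consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DriftConfig", "DriftTrajectory", "simulate_drift", "apply_drift"]


@dataclass(frozen=True)
class DriftConfig:
    mean_velocity: tuple = (1.0, 1.0)  # nm/s per axis (2D or 3D)
    drag_coefficient: float = 0.5  # 1/s
    random_force_sigma: float = 0.5  # nm / s^(3/2)
    frame_time: float = 0.1  # s
    n_frames: int = 1000

    def __post_init__(self):
        if self.drag_coefficient < 0 or self.random_force_sigma < 0:
            raise ValueError("drag and random-force sigma must be >= 0")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class DriftTrajectory:
    """Per-frame offsets (nm) and velocities (nm/s); offsets[0] = 0."""

    offsets: np.ndarray  # (n_frames, dim)
    velocities: np.ndarray  # (n_frames, dim)
    frame_time: float

    def __post_init__(self):
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        if self.offsets.shape != self.velocities.shape:
            raise ValueError("offsets and velocities must have the same shape")
        if np.any(np.abs(self.offsets[0]) > 1e-12):
            raise ValueError("offsets must start at zero")

    @property
    def n_frames(self) -> int:
        return self.offsets.shape[0]


def simulate_drift(cfg: DriftConfig, rng_seed) -> DriftTrajectory:
    """Simulate an Ornstein-Uhlenbeck velocity drift trajectory.

    With ``random_force_sigma == 0`` the trajectory is exactly linear at the
    mean velocity.  The initial velocity is the mean velocity.
    """
    rng = np.random.default_rng(rng_seed)
    v_mean = np.atleast_1d(np.asarray(cfg.mean_velocity, dtype=float))
    dim = v_mean.shape[0]
    n = cfg.n_frames
    dt = cfg.frame_time
    v = np.empty((n, dim))
    v[0] = v_mean
    if cfg.random_force_sigma > 0:
        noise = rng.standard_normal((n - 1, dim)) if n > 1 else np.empty((0, dim))
    else:
        noise = np.zeros((max(n - 1, 0), dim))
    k = cfg.drag_coefficient
    s = cfg.random_force_sigma
    for t in range(n - 1):
        v[t + 1] = v[t] - k * (v[t] - v_mean) * dt + s * np.sqrt(dt) * noise[t]
    offsets = np.vstack([np.zeros(dim), np.cumsum(v[:-1] * dt, axis=0)]) if n > 1 else np.zeros((1, dim))
    return DriftTrajectory(offsets=offsets, velocities=v, frame_time=dt)


def apply_drift(events, traj: DriftTrajectory):
    """Shift event positions by the drift offset of their starting frame.

    Returns new events (inputs are not modified); the undrifted position is
    recorded separately by the ground-truth writer.  Sub-frame motion blur
    is not modelled: an event uses the offset of the frame it starts in.
    Raises if an event's frames fall outside the trajectory.
    """
    import copy

    out = []
    dim = traj.offsets.shape[1]
    for ev in events:
        if ev.frame_start < 0 or ev.frame_end >= traj.n_frames:
            raise ValueError(
                f"event frames [{ev.frame_start}, {ev.frame_end}] outside trajectory"
            )
        new = copy.copy(ev)
        new.position = ev.position.copy()
        new.position[:dim] += traj.offsets[ev.frame_start]
        out.append(new)
    return out
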