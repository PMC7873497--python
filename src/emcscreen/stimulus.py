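"""Target trajectories for the continuous tracking task.

The tracking paradigm shows a small luminance blob that either drifts
continuously according to a two-dimensional Gaussian random walk
("smooth" mode, eliciting smooth pursuit) or additionally jumps to a
random screen location at a fixed interval ("displaced" mode, eliciting
saccadic reacquisition).  A session consists of several independent
trials of fixed duration sampled at the display refresh rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = [
    "SMOOTH",
    "DISPLACED",
    "MODES",
    "SessionConfig",
    "StimulusTrajectory",
    "generate_trajectory",
    "generate_session",
]

SMOOTH = "smooth"
DISPLACED = "displaced"
MODES = (SMOOTH, DISPLACED)


class ConfigurationError(ValueError):
    """Raised when a session configuration violates its invariants."""


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one recording session.

    Parameters
    ----------
    n_trials
        Number of independent trials per session.
    trial_duration
        Trial length in seconds.
    rate
        Sampling / display rate in Hz.
    jump_interval
        Seconds between target relocations (displaced mode only).
    step_sd
        Standard deviation of each random-walk step, in degrees per
        sample and per axis.
    bounds
        Half-extent of the display in degrees; the walk is reflected at
        ``±bounds`` and displaced-mode jump destinations are drawn
        uniformly from ``[-bounds, bounds]`` per axis.
    seed
        Seed for the session's random draws.
    """

    n_trials: int = 6
    trial_duration: float = 20.0
    rate: float = 60.0
    jump_interval: float = 2.0
    step_sd: float = 0.25
    bounds: float = 15.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not self.trial_duration > 0:
            raise ConfigurationError("trial_duration must be positive")
        if not self.rate > 0:
            raise ConfigurationError("rate must be positive")
        if not self.jump_interval > 0:
            raise ConfigurationError("jump_interval must be positive")
        if self.step_sd < 0:
            raise ConfigurationError("step_sd must be >= 0")
        if not self.bounds > 0:
            raise ConfigurationError("bounds must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.rate))

    @property
    def jump_period_samples(self) -> int:
        return int(round(self.jump_interval * self.rate))


@dataclass
class StimulusTrajectory:
    """Target positions of one trial, in visual degrees."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mode: str
    rate: float
    jump_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.jump_indices = np.asarray(self.jump_indices, dtype=int)
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        n = self.timestamps.size
        if self.x.size != n or self.y.size != n:
            raise ConfigurationError("x, y and timestamps must share length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ConfigurationError("positions must be finite")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def _reflect(positions: np.ndarray, bounds: float) -> np.ndarray:
    """Fold a free random walk into ``[-bounds, bounds]`` by reflection."""
    period = 4.0 * bounds
    folded = np.mod(positions + bounds, period)
    folded = np.where(folded > 2.0 * bounds, period - folded, folded)
    return folded - bounds


def _walk(
    rng: np.random.Generator, n: int, start: float, step_sd: float, bounds: float
) -> np.ndarray:
    steps = rng.normal(0.0, step_sd, size=n)
    steps[0] = 0.0
    return _reflect(start + np.cumsum(steps), bounds)


def generate_trajectory(
    config: SessionConfig,
    mode: str,
    rng: Optional[np.random.Generator] = None,
) -> StimulusTrajectory:
    """Generate one trial's target trajectory.

    Smooth mode is a per-axis Gaussian random walk reflected at the
    display bounds.  Displaced mode follows the same walk but relocates
    the target to a uniform random on-screen position every
    ``config.jump_interval`` seconds; between jumps the walk law is
    unchanged.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if n < 1:
        raise ConfigurationError("trial has no samples")
    timestamps = np.arange(n) / config.rate

    start = rng.uniform(-config.bounds, config.bounds, size=2)
    if mode == SMOOTH:
        x = _walk(rng, n, start[0], config.step_sd, config.bounds)
        y = _walk(rng, n, start[1], config.step_sd, config.bounds)
        jumps = np.empty(0, dtype=int)
    else:
        period = config.jump_period_samples
        jumps = np.arange(period, n, period, dtype=int)
        x = np.empty(n)
        y = np.empty(n)
        seg_starts = np.concatenate(([0], jumps))
        seg_ends = np.concatenate((jumps, [n]))
        sx, sy = start
        for s, e in zip(seg_starts, seg_ends):
            if s > 0:  # relocation at the jump instant
                sx, sy = rng.uniform(-config.bounds, config.bounds, size=2)
            x[s:e] = _walk(rng, e - s, sx, config.step_sd, config.bounds)
            y[s:e] = _walk(rng, e - s, sy, config.step_sd, config.bounds)
    return StimulusTrajectory(
        timestamps=timestamps, x=x, y=y, mode=mode, rate=config.rate,
        jump_indices=jumps,
    )


def generate_session(
    config: SessionConfig,
    mode: str,
    rng: Optional[np.random.Generator] = None,
) -> List[StimulusTrajectory]:
    """Generate ``config.n_trials`` independent trajectories.

    Deterministic given ``config.seed`` (or the supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [generate_trajectory(config, mode, rng) for _ in range(config.n_trials)]
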