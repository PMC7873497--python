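"""Simulated gaze responses with known ground-truth parameters.

There is no deposited patient data for this paradigm, so every
downstream stage (preprocessing, correlogram features, normative
scoring, classification) is validated by parameter recovery on
simulated observers.  An observer tracks the target with a pursuit
latency and gain, carries additive positional noise, occasionally
blinks (producing the upward-spike-then-dropout artifact of video eye
trackers), and — in displaced mode — needs extra time to reacquire the
target after each jump, during which gaze lingers near the pre-jump
position with elevated "search" noise.

Default phenotypes emulate the qualitative group patterns reported for
this task: controls track with short latency in both modes;
glaucoma-like observers pursue normally but reacquire slowly and
imprecisely after jumps (peripheral field loss); neuro-like observers
show elevated latency and spatial/temporal uncertainty in both modes.
The parameter values are configuration, not clinical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .stimulus import (
    DISPLACED,
    SMOOTH,
    SessionConfig,
    StimulusTrajectory,
    generate_trajectory,
)

__all__ = [
    "ObserverModel",
    "GazeRecording",
    "ParticipantRecord",
    "simulate_gaze",
    "inject_blink",
    "generate_cohort",
    "default_phenotypes",
]

#: vertical ramp speed of the injected blink artifact, deg/s.  Must
#: comfortably exceed the 190 deg/s detector threshold.
BLINK_SPIKE_VELOCITY = 300.0
#: number of ramp samples at the start of an injected blink.
BLINK_SPIKE_SAMPLES = 3


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth tracking parameters of one simulated participant."""

    lag: float = 0.18  #: pursuit latency, s
    gain: float = 1.0  #: pursuit gain (gaze amplitude / target amplitude)
    noise_sd: float = 0.5  #: additive positional noise, deg
    blink_rate: float = 0.1  #: blink events per second
    blink_duration: float = 0.2  #: seconds of artifact per blink
    reacquisition_delay: float = 0.0  #: extra delay after displaced jumps, s
    search_noise_sd: float = 0.0  #: extra noise while reacquiring, deg
    #: SD (s) of the zero-phase Gaussian kernel smoothing the pursuit
    #: response.  The oculomotor plant low-pass filters target motion;
    #: this is what gives the velocity correlogram its Gaussian width
    #: (the "temporal uncertainty").  Zero-phase, so ``lag`` remains the
    #: sole source of delay.
    motor_smoothing: float = 0.04
    #: per-jump SD (s) of the reacquisition delay: saccadic latencies
    #: vary from jump to jump, spreading the displaced-mode correlogram.
    reacquisition_jitter: float = 0.05

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
            if f.name != "gain" and v < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass
class GazeRecording:
    """Measured gaze positions, same clock as the paired stimulus.

    Invalid samples carry NaN in both coordinates and ``valid=False``.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float
    units: str = "deg"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.timestamps.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("all series must share length")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            self.timestamps.copy(), self.x.copy(), self.y.copy(),
            self.valid.copy(), self.rate, self.units,
        )


def _lagged(series: np.ndarray, lag_samples: int) -> np.ndarray:
    """Shift a series later in time, holding the first value early on."""
    if lag_samples == 0:
        return series.copy()
    out = np.empty_like(series)
    out[:lag_samples] = series[0]
    out[lag_samples:] = series[:-lag_samples]
    return out


def simulate_gaze(
    stimulus: StimulusTrajectory,
    observer: ObserverModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> GazeRecording:
    """Simulate a gaze recording for one trial.

    The response is ``gain × stimulus(t − lag)`` plus Gaussian
    positional noise.  After each displaced-mode jump the observer
    holds its pre-jump position estimate for ``reacquisition_delay``
    seconds with ``search_noise_sd`` extra noise before resuming
    tracking.  Blinks arrive as a Poisson process and are injected via
    :func:`inject_blink`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rate = stimulus.rate
    n = stimulus.n_samples
    lag_samples = int(round(observer.lag * rate))
    if lag_samples >= n:
        raise ValueError("pursuit lag exceeds the trial duration")

    sx, sy = stimulus.x, stimulus.y
    if observer.motor_smoothing > 0:
        sigma = observer.motor_smoothing * rate
        sx = ndimage.gaussian_filter1d(sx, sigma, mode="nearest")
        sy = ndimage.gaussian_filter1d(sy, sigma, mode="nearest")
    gx = observer.gain * _lagged(sx, lag_samples)
    gy = observer.gain * _lagged(sy, lag_samples)
    extra_sd = np.zeros(n)

    if stimulus.mode == DISPLACED and (
            observer.reacquisition_delay > 0 or observer.reacquisition_jitter > 0):
        for j in stimulus.jump_indices:
            delay = max(0.0, observer.reacquisition_delay
                        + rng.normal(0.0, observer.reacquisition_jitter))
            reacq = int(round(delay * rate))
            s = j + lag_samples  # jump becomes visible in the lagged response
            e = min(s + reacq, n)
            if s >= n or s < 1 or reacq == 0:
                continue
            gx[s:e] = gx[s - 1]
            gy[s:e] = gy[s - 1]
            extra_sd[s:e] = observer.search_noise_sd

    gx = gx + rng.normal(0.0, 1.0, n) * np.hypot(observer.noise_sd, extra_sd)
    gy = gy + rng.normal(0.0, 1.0, n) * np.hypot(observer.noise_sd, extra_sd)

    gaze = GazeRecording(
        timestamps=stimulus.timestamps.copy(),
        x=gx, y=gy, valid=np.ones(n, dtype=bool), rate=rate,
    )

    dur_samples = int(round(observer.blink_duration * rate))
    if observer.blink_rate > 0 and dur_samples > 0:
        n_blinks = rng.poisson(observer.blink_rate * stimulus.duration)
        if n_blinks > 0:
            starts = np.sort(
                rng.integers(0, max(1, n - dur_samples), size=n_blinks)
            )
            last_end = -10 * dur_samples
            for s in starts:
                if s < last_end + dur_samples:  # keep events disjoint
                    continue
                gaze = inject_blink(gaze, int(s), dur_samples)
                last_end = int(s) + dur_samples
    return gaze


def inject_blink(
    gaze: GazeRecording, start: int, duration: int
) -> GazeRecording:
    """Inject one video-eye-tracker blink artifact.

    The closing eyelid makes the tracker report the pupil shooting
    upward: the vertical position ramps up for a few samples at a
    vertical velocity well above 190 deg/s, after which samples are
    missing until the eye reopens.
    """
    if duration == 0:
        return gaze
    n = gaze.n_samples
    if duration < 0 or start < 0 or start + duration > n:
        raise ValueError("blink segment out of range")
    out = gaze.copy()
    spike = min(BLINK_SPIKE_SAMPLES, duration)
    step = BLINK_SPIKE_VELOCITY / gaze.rate
    base = out.y[start]
    if not np.isfinite(base):
        base = 0.0
    for k in range(spike):
        out.y[start + k] = base + (k + 1) * step
    lost = slice(start + spike, start + duration)
    out.x[lost] = np.nan
    out.y[lost] = np.nan
    out.valid[lost] = False
    return out


@dataclass
class ParticipantRecord:
    """One simulated participant: label, true parameters, both sessions."""

    participant_id: str
    label: str
    observer: ObserverModel
    sessions: Dict[str, List[Tuple[StimulusTrajectory, GazeRecording]]]


def default_phenotypes(
    n_control: int = 20, n_glaucoma: int = 20, n_neuro: int = 20
) -> List[Tuple[str, ObserverModel, int]]:
    """Three observer phenotypes mirroring the qualitative group patterns."""
    control = ObserverModel(
        lag=0.18, noise_sd=0.5, blink_rate=0.15, blink_duration=0.2,
        reacquisition_delay=0.12, search_noise_sd=0.5,
        motor_smoothing=0.04, reacquisition_jitter=0.04,
    )
    glaucoma = ObserverModel(
        lag=0.20, noise_sd=0.7, blink_rate=0.15, blink_duration=0.2,
        reacquisition_delay=0.45, search_noise_sd=3.0,
        motor_smoothing=0.05, reacquisition_jitter=0.10,
    )
    neuro = ObserverModel(
        lag=0.33, noise_sd=2.0, blink_rate=0.15, blink_duration=0.2,
        reacquisition_delay=0.25, search_noise_sd=1.5,
        motor_smoothing=0.08, reacquisition_jitter=0.07,
    )
    return [
        ("control", control, n_control),
        ("glaucoma", glaucoma, n_glaucoma),
        ("neuro", neuro, n_neuro),
    ]


def _jitter_observer(
    observer: ObserverModel, rng: np.random.Generator, jitter_rel: float
) -> ObserverModel:
    """Multiplicative per-participant jitter, truncated at zero."""
    if jitter_rel == 0:
        return observer
    kwargs = {}
    for f in fields(observer):
        v = getattr(observer, f.name)
        kwargs[f.name] = max(0.0, v * (1.0 + rng.normal(0.0, jitter_rel)))
    return ObserverModel(**kwargs)


def generate_cohort(
    phenotypes: Sequence[Tuple[str, ObserverModel, int]],
    config: SessionConfig,
    seed: Optional[int] = None,
    jitter_rel: float = 0.1,
) -> List[ParticipantRecord]:
    """Simulate a labelled cohort.

    Each participant runs one smooth and one displaced session with
    per-participant multiplicative parameter jitter
    (``jitter_rel`` relative SD).  Deterministic given ``seed``.
    """
    if not phenotypes:
        raise ValueError("phenotype list must be non-empty")
    for label, _, count in phenotypes:
        if count < 1:
            raise ValueError(f"count for {label!r} must be >= 1")
    rng = np.random.default_rng(seed)
    cohort: List[ParticipantRecord] = []
    idx = 0
    for label, base, count in phenotypes:
        for _ in range(count):
            obs = _jitter_observer(base, rng, jitter_rel)
            sessions: Dict[str, List[Tuple[StimulusTrajectory, GazeRecording]]] = {}
            for mode in (SMOOTH, DISPLACED):
                trials = []
                for _trial in range(config.n_trials):
                    stim = generate_trajectory(config, mode, rng)
                    gaze = simulate_gaze(stim, obs, rng=rng)
                    trials.append((stim, gaze))
                sessions[mode] = trials
            cohort.append(
                ParticipantRecord(f"P{idx:03d}", label, obs, sessions)
            )
            idx += 1
    return cohort
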