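"""Spatiotemporal properties (STP) of tracking eye movements.

The eye-movement correlogram (EMC) correlates stimulus and gaze
*velocities* as a function of time lag; a Gaussian fitted to the
trial-averaged cross-correlogram (CCG) yields the temporal properties
(amplitude = peak velocity correlation, mean = pursuit latency,
SD = temporal uncertainty, adjusted R² = goodness of the Gaussian
description).  The positional error distribution (PED) — a unit-mass
histogram of per-sample gaze-minus-stimulus deviations pooled over
trials, also Gaussian-fitted — yields the spatial properties.  Two
integrated properties complete the set: the cosine similarity between
stimulus and gaze position vectors, and the observation-noise variance
obtained by running a Kalman filter "in reverse": with the target's
random-walk step variance known, the observation-noise variance R that
maximises the innovations likelihood of the gaze series measures the
observer's sensory noise.

Ten properties × two axes (horizontal, vertical) × two stimulus modes
(smooth, displaced) give the 40-dimensional feature vector used for
screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal

from .preprocess import CleanTrial
from .stimulus import DISPLACED, SMOOTH

__all__ = [
    "Correlogram",
    "GaussianFit",
    "ErrorDistribution",
    "KalmanNoiseEstimate",
    "STPFeatures",
    "FEATURE_NAMES",
    "FitError",
    "cross_correlogram",
    "average_correlograms",
    "fit_gaussian",
    "positional_error_distribution",
    "cosine_similarity",
    "observation_noise_variance",
    "extract_features",
]

PROPERTIES = (
    "ped_amplitude", "ped_mean", "ped_sd", "ped_adj_r2",
    "ccg_amplitude", "ccg_mean", "ccg_sd", "ccg_adj_r2",
    "noise_variance", "cosine_similarity",
)
AXES = ("horizontal", "vertical")
MODES = (SMOOTH, DISPLACED)

#: Canonical feature order: property-major, then axis, then mode.
FEATURE_NAMES: Tuple[str, ...] = tuple(
    f"{prop}_{axis}_{mode}"
    for prop in PROPERTIES for axis in AXES for mode in MODES
)

DEFAULT_BIN_WIDTH = 0.5  # deg
DEFAULT_BIN_RANGE = 30.0  # deg, histogram spans ±this
DEFAULT_MAX_LAG = 1.0  # s, CCG lag window


class FitError(RuntimeError):
    """A curve fit or likelihood maximisation could not be completed."""


@dataclass
class Correlogram:
    """Velocity cross-correlation as a function of time lag.

    Positive lags mean the gaze follows the stimulus.
    """

    lags: np.ndarray  # seconds, symmetric about 0, uniform step
    r: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.lags.size != self.r.size:
            raise ValueError("lags and r must share length")

    @property
    def peak_lag(self) -> float:
        return float(self.lags[int(np.argmax(self.r))])


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of a least-squares 1-D Gaussian fit."""

    amplitude: float
    mean: float
    sd: float
    adj_r2: float


@dataclass
class ErrorDistribution:
    """Unit-mass histogram of positional errors with its Gaussian fit."""

    bin_centers: np.ndarray
    probability: np.ndarray
    fit: GaussianFit


@dataclass(frozen=True)
class KalmanNoiseEstimate:
    """Observation-noise variance from the reversed Kalman filter."""

    observation_noise_variance: float  # R, deg²
    target_displacement_variance: float  # Q, deg²
    log_likelihood: float


def cross_correlogram(
    stim_vel: np.ndarray,
    gaze_vel: np.ndarray,
    rate: float = 60.0,
    max_lag: float = DEFAULT_MAX_LAG,
) -> Correlogram:
    """Normalized (Pearson) velocity cross-correlation per lag.

    ``r(τ)`` is the Pearson correlation between the gaze velocity and
    the stimulus velocity shifted by ``τ``, computed over the
    overlapping samples, for ``τ`` from ``−max_lag`` to ``+max_lag`` in
    steps of one sample interval.
    """
    s = np.asarray(stim_vel, dtype=float)
    g = np.asarray(gaze_vel, dtype=float)
    if s.size != g.size:
        raise ValueError("series must have equal length")
    n = s.size
    max_shift = int(round(max_lag * rate))
    if n <= 2 * max_shift:
        raise ValueError("series shorter than the lag window")
    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.empty(shifts.size)
    for i, k in enumerate(shifts):
        if k >= 0:
            a, b = g[k:], s[: n - k]
        else:
            a, b = g[: n + k], s[-k:]
        a = a - a.mean()
        b = b - b.mean()
        denom = math.sqrt(float(a @ a) * float(b @ b))
        if denom == 0.0:
            raise ValueError("zero-variance overlap: correlation undefined")
        r[i] = float(a @ b) / denom
    return Correlogram(lags=shifts / rate, r=r)


def average_correlograms(correlograms: Sequence[Correlogram]) -> Correlogram:
    """Pointwise mean of per-trial correlograms on a shared lag grid."""
    if not correlograms:
        raise ValueError("need at least one correlogram")
    lags = correlograms[0].lags
    for c in correlograms[1:]:
        if c.lags.size != lags.size or not np.allclose(c.lags, lags):
            raise ValueError("correlograms have mismatched lag grids")
    return Correlogram(
        lags=lags.copy(),
        r=np.mean([c.r for c in correlograms], axis=0),
    )


def _gauss(x: np.ndarray, a: float, mu: float, sd: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))


def fit_gaussian(x: np.ndarray, y: np.ndarray) -> GaussianFit:
    """Least-squares fit of ``y ≈ A·exp(−(x−μ)²/(2σ²))``.

    Initialised at the curve's peak with a half-width-at-half-maximum
    σ guess; μ is constrained to the x-range.  ``adj_r2`` applies the
    three-parameter small-sample correction to R².
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise FitError("need at least 4 points")
    if np.ptp(y) == 0.0:
        raise FitError("flat input: no curve to fit")
    i0 = int(np.argmax(np.abs(y)))
    a0 = float(y[i0])
    mu0 = float(x[i0])
    half = abs(a0) / 2.0
    above = np.abs(y) >= half
    span = x[above]
    sd0 = max((span.max() - span.min()) / 2.355, np.ptp(x) / max(x.size - 1, 1))
    dx = np.ptp(x)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=[a0, mu0, sd0],
            bounds=([-np.inf, x.min(), 1e-12], [np.inf, x.max(), 10.0 * dx]),
            xtol=1e-10, ftol=1e-10, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit failed: {exc}") from exc
    a, mu, sd = (float(v) for v in popt)
    resid = y - _gauss(x, a, mu, sd)
    ss_res = float(resid @ resid)
    ybar = y - y.mean()
    ss_tot = float(ybar @ ybar)
    if ss_tot == 0.0:
        raise FitError("zero total variance")
    r2 = 1.0 - ss_res / ss_tot
    n, p = x.size, 3
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return GaussianFit(amplitude=a, mean=mu, sd=abs(sd), adj_r2=adj_r2)


def positional_error_distribution(
    errors: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_range: float = DEFAULT_BIN_RANGE,
) -> ErrorDistribution:
    """Histogram + Gaussian fit of pooled signed positional errors.

    ``errors`` are per-sample gaze − stimulus deviations on one axis,
    concatenated across the valid trials of a mode.  The histogram has
    unit total mass; spatial properties are read off the fitted curve.
    """
    errors = np.asarray(errors, dtype=float)
    errors = errors[np.isfinite(errors)]
    if errors.size == 0:
        raise ValueError("no finite error samples")
    # bins centred on zero so perfect tracking occupies the zero bin
    edges = np.arange(-bin_range - bin_width / 2.0,
                      bin_range + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(errors, -bin_range, bin_range), bins=edges)
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    fit = fit_gaussian(centers, prob)
    return ErrorDistribution(bin_centers=centers, probability=prob, fit=fit)


def cosine_similarity(stim_pos: np.ndarray, gaze_pos: np.ndarray) -> float:
    """Inner product of the two position vectors over their magnitudes."""
    s = np.asarray(stim_pos, dtype=float)
    g = np.asarray(gaze_pos, dtype=float)
    if s.size != g.size:
        raise ValueError("vectors must have equal length")
    ns = float(np.linalg.norm(s))
    ng = float(np.linalg.norm(g))
    if ns == 0.0 or ng == 0.0:
        raise ValueError("zero-magnitude vector")
    return float(s @ g) / (ns * ng)


# --- reversed Kalman filter ------------------------------------------------

_STEADY_STATE_BURN = 400  # exact time-varying steps before the steady-state tail


def _local_level_loglik(y: np.ndarray, q: float, r: float) -> float:
    """Innovations log-likelihood of a local-level model.

    State: ``x_t = x_{t−1} + w_t`` with ``w ~ N(0, q)``; observation
    ``y_t = x_t + v_t`` with ``v ~ N(0, r)``.  The level is initialised
    from the first observation (which is therefore not scored).  The
    gain recursion is data-independent and converges geometrically, so
    after a burn-in of exact steps the remaining innovations are
    produced with the steady-state gain via a linear filter.
    """
    n = y.size
    a = float(y[0])
    p = q + r
    ll = 0.0
    burn = min(n - 1, _STEADY_STATE_BURN)
    log2pi = math.log(2.0 * math.pi)
    for t in range(1, burn + 1):
        f = p + r
        v = float(y[t]) - a
        ll += log2pi + math.log(f) + v * v / f
        k = p / f
        a += k * v
        p = p * (1.0 - k) + q
    if burn < n - 1:
        f = p + r
        k = p / f
        tail = y[burn + 1:]
        if tail.size > 1:
            pred, _ = signal.lfilter(
                [k], [1.0, -(1.0 - k)], tail[:-1], zi=[(1.0 - k) * a]
            )
            preds = np.concatenate(([a], pred))
        else:
            preds = np.array([a])
        v = tail - preds
        ll += v.size * (log2pi + math.log(f)) + float(v @ v) / f
    return -0.5 * ll


def observation_noise_variance(
    stim_pos: np.ndarray,
    gaze_pos: np.ndarray,
    q: Optional[float] = None,
    r_bounds: Tuple[float, float] = (1e-10, 1e4),
) -> KalmanNoiseEstimate:
    """Estimate the observer's sensory noise by reversing a Kalman filter.

    The target's displacement variance Q is taken as the empirical
    variance of the stimulus position increments (or supplied); the
    returned R maximises the innovations log-likelihood of the gaze
    series under the local-level model, found by a bounded 1-D search
    over log R.
    """
    s = np.asarray(stim_pos, dtype=float)
    g = np.asarray(gaze_pos, dtype=float)
    if s.size != g.size:
        raise ValueError("series must have equal length")
    if g.size < 100:
        raise ValueError("need at least 100 samples")
    if q is None:
        q = float(np.var(np.diff(s)))
    if not np.all(np.isfinite(g)):
        raise ValueError("gaze series contains non-finite values")

    lo, hi = (math.log(b) for b in r_bounds)

    def neg_ll(log_r: float) -> float:
        val = _local_level_loglik(g, q, math.exp(log_r))
        if not np.isfinite(val):
            raise FitError("non-finite likelihood")
        return -val

    res = optimize.minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    r_hat = float(math.exp(res.x))
    return KalmanNoiseEstimate(
        observation_noise_variance=r_hat,
        target_displacement_variance=q,
        log_likelihood=float(-res.fun),
    )


# --- feature assembly ------------------------------------------------------

@dataclass
class STPFeatures:
    """The named 40-value feature vector plus extraction metadata.

    Failed sub-computations are recorded as NaN with a reason in
    ``warnings``; ranges bounded by construction (PED amplitude and
    cosine similarity in [0, 1]) are enforced by clipping, with a
    warning when clipping fired.
    """

    values: Dict[str, float]
    metadata: Dict[str, object] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(
                f"feature vector must carry exactly the canonical 40 names; "
                f"missing={missing[:3]}, extra={extra[:3]}"
            )
        self.values = {n: float(self.values[n]) for n in FEATURE_NAMES}

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])

    @classmethod
    def from_dict(cls, values: Dict[str, float], **meta) -> "STPFeatures":
        return cls(values={n: float(values[n]) for n in FEATURE_NAMES},
                   metadata=dict(meta))


def _axis_series(trial: CleanTrial, axis: str):
    if axis == "horizontal":
        return trial.x, trial.stim_x, trial.vx, trial.stim_vx
    return trial.y, trial.stim_y, trial.vy, trial.stim_vy


def extract_features(
    smooth_trials: Sequence[CleanTrial],
    displaced_trials: Sequence[CleanTrial],
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_range: float = DEFAULT_BIN_RANGE,
    max_lag: float = DEFAULT_MAX_LAG,
) -> STPFeatures:
    """Assemble the 40 spatiotemporal properties of one participant.

    Per axis and mode: four spatial properties from the pooled
    positional error distribution, four temporal properties from the
    Gaussian fit to the trial-averaged velocity CCG, the
    observation-noise variance, and the cosine similarity.  Only trials
    that survived preprocessing contribute.
    """
    sessions = {SMOOTH: list(smooth_trials), DISPLACED: list(displaced_trials)}
    values: Dict[str, float] = {}
    warnings: List[str] = []
    valid_counts = {}
    for mode, trials in sessions.items():
        valid = [t for t in trials if t.valid]
        valid_counts[mode] = len(valid)
        if not valid:
            raise ValueError(f"no valid trials in {mode} session")
        rate = valid[0].rate
        for axis in AXES:
            key = f"{axis}_{mode}"
            gaze_pos, stim_pos, gaze_vel, stim_vel = zip(
                *(_axis_series(t, axis) for t in valid)
            )
            errors = np.concatenate(
                [g - s for g, s in zip(gaze_pos, stim_pos)]
            )
            # spatial properties
            try:
                ped = positional_error_distribution(errors, bin_width, bin_range)
                amp = ped.fit.amplitude
                if not 0.0 <= amp <= 1.0:
                    warnings.append(f"ped_amplitude_{key} clipped into [0, 1]")
                    amp = float(np.clip(amp, 0.0, 1.0))
                values[f"ped_amplitude_{key}"] = amp
                values[f"ped_mean_{key}"] = abs(ped.fit.mean)
                values[f"ped_sd_{key}"] = ped.fit.sd
                values[f"ped_adj_r2_{key}"] = ped.fit.adj_r2
            except (FitError, ValueError) as exc:
                warnings.append(f"PED {key}: {exc}")
                for prop in ("ped_amplitude", "ped_mean", "ped_sd", "ped_adj_r2"):
                    values[f"{prop}_{key}"] = float("nan")
            # temporal properties
            try:
                ccgs = [
                    cross_correlogram(sv, gv, rate, max_lag)
                    for sv, gv in zip(stim_vel, gaze_vel)
                ]
                avg = average_correlograms(ccgs)
                gf = fit_gaussian(avg.lags, avg.r)
                amp = gf.amplitude
                if not -1.0 <= amp <= 1.0:
                    warnings.append(f"ccg_amplitude_{key} clipped into [-1, 1]")
                    amp = float(np.clip(amp, -1.0, 1.0))
                values[f"ccg_amplitude_{key}"] = amp
                values[f"ccg_mean_{key}"] = gf.mean
                values[f"ccg_sd_{key}"] = gf.sd
                values[f"ccg_adj_r2_{key}"] = gf.adj_r2
            except (FitError, ValueError) as exc:
                warnings.append(f"CCG {key}: {exc}")
                for prop in ("ccg_amplitude", "ccg_mean", "ccg_sd", "ccg_adj_r2"):
                    values[f"{prop}_{key}"] = float("nan")
            # integrated properties
            stim_cat = np.concatenate(stim_pos)
            gaze_cat = np.concatenate(gaze_pos)
            try:
                kal = observation_noise_variance(stim_cat, gaze_cat)
                values[f"noise_variance_{key}"] = kal.observation_noise_variance
            except (FitError, ValueError) as exc:
                warnings.append(f"Kalman {key}: {exc}")
                values[f"noise_variance_{key}"] = float("nan")
            try:
                cs = cosine_similarity(stim_cat, gaze_cat)
                if cs < 0.0:
                    warnings.append(
                        f"cosine_similarity_{key} negative "
                        f"(anti-correlated tracking), clipped to 0"
                    )
                    cs = 0.0
                values[f"cosine_similarity_{key}"] = cs
            except ValueError as exc:
                warnings.append(f"cosine {key}: {exc}")
                values[f"cosine_similarity_{key}"] = float("nan")
    return STPFeatures(
        values=values,
        metadata={
            "bin_width": bin_width,
            "bin_range": bin_range,
            "max_lag": max_lag,
            "valid_trials": valid_counts,
        },
        warnings=warnings,
    )
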