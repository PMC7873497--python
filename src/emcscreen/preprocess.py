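"""Gaze preprocessing: coordinate conversion, blink repair, velocities.

Raw recordings arrive as screen coordinates with a per-sample validity
flag.  The cleaning pipeline (1) converts to visual-field coordinates
(degrees, origin at screen centre), (2) differentiates to velocities,
(3) detects the blink artifact of video eye trackers — a vertical
velocity spike above 190 deg/s followed by a flat line or missing data
— dilating each detection by five samples, (4) fills the affected
samples from forward and reverse autoregressive extrapolations fitted
on 10-sample context windows, and finally rejects any trial whose
blink/missing losses exceed one third of its duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .observer import GazeRecording
from .stimulus import StimulusTrajectory

__all__ = [
    "ScreenGeometry",
    "BlinkSegment",
    "CleanTrial",
    "screen_to_degrees",
    "degrees_to_screen",
    "compute_velocity",
    "detect_blinks",
    "fill_missing_ar",
    "trial_is_valid",
    "preprocess_trial",
]

BLINK_VELOCITY_THRESHOLD = 190.0  # deg/s, vertical upward spike
BLINK_DILATION = 5  # samples added on each side of a detection
AR_CONTEXT = 10  # samples of context for the autoregressive fill
AR_ORDER = 2
MAX_LOSS_FRACTION = 0.33  # trials losing more than this are discarded
FLAT_TOL = 1e-6  # deg/s; |Δv| below this counts as a flat line
FLAT_MIN_RUN = 2  # consecutive flat differences required


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used for the pixel↔degree mapping."""

    width_px: float = 1280.0
    height_px: float = 1024.0
    width_mm: float = 340.0
    height_mm: float = 270.0
    viewing_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        for v in (self.width_px, self.height_px, self.width_mm,
                  self.height_mm, self.viewing_distance_mm):
            if not v > 0:
                raise ValueError("geometry fields must be positive")


@dataclass(frozen=True)
class BlinkSegment:
    """Inclusive sample range covered by one (dilated) blink."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError("invalid blink segment")

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


def screen_to_degrees(x_px, y_px, geometry: ScreenGeometry):
    """Map screen pixels to visual-field degrees.

    Origin at screen centre; rightward and upward positive (screen
    pixel rows grow downward, hence the vertical sign flip).  The
    per-axis angle is ``atan(offset_mm / viewing_distance_mm)``.
    """
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    dx_mm = (x_px - geometry.width_px / 2.0) * geometry.width_mm / geometry.width_px
    dy_mm = (geometry.height_px / 2.0 - y_px) * geometry.height_mm / geometry.height_px
    x_deg = np.degrees(np.arctan(dx_mm / geometry.viewing_distance_mm))
    y_deg = np.degrees(np.arctan(dy_mm / geometry.viewing_distance_mm))
    return x_deg, y_deg


def degrees_to_screen(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`screen_to_degrees`."""
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.asarray(y_deg, dtype=float)
    dx_mm = np.tan(np.radians(x_deg)) * geometry.viewing_distance_mm
    dy_mm = np.tan(np.radians(y_deg)) * geometry.viewing_distance_mm
    x_px = dx_mm * geometry.width_px / geometry.width_mm + geometry.width_px / 2.0
    y_px = geometry.height_px / 2.0 - dy_mm * geometry.height_px / geometry.height_mm
    return x_px, y_px


def compute_velocity(positions: np.ndarray, rate: float) -> np.ndarray:
    """First-difference velocity in deg/s.

    The difference is assigned to the later sample and the series is
    front-padded with its first value, so position and velocity share
    indexing and length.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    v = np.diff(positions) * rate
    return np.concatenate(([v[0]], v))


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_blinks(
    vertical_velocity: np.ndarray,
    valid: Optional[np.ndarray] = None,
    threshold: float = BLINK_VELOCITY_THRESHOLD,
    dilation: int = BLINK_DILATION,
    flat_tol: float = FLAT_TOL,
) -> List[BlinkSegment]:
    """Find blink artifacts in the vertical velocity trace.

    A super-threshold upward spike is flagged only when it is followed
    by a flat line (derivative of the velocity numerically zero over at
    least :data:`FLAT_MIN_RUN` samples) or by missing data — isolated
    fast upward movements with normal dynamics afterwards are left
    alone.  Each flagged region (spike plus the trailing flat/missing
    run) is dilated by ``dilation`` samples on both sides; overlapping
    segments are merged.
    """
    vv = np.asarray(vertical_velocity, dtype=float)
    n = vv.size
    if n == 0:
        raise ValueError("empty velocity series")
    if valid is None:
        valid = np.isfinite(vv)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(vv)

    spike = (vv > threshold) & valid
    missing = ~valid

    raw: List[Tuple[int, int]] = []
    for s, e in _runs(spike):
        # walk forward from the spike through any missing and/or flat run
        j = e + 1
        saw_missing = False
        flat_samples = 0  # samples covered by a flat line
        tail_end = e
        while j < n:
            if missing[j]:
                saw_missing = True
                tail_end = j
                j += 1
            elif (j + 1 < n and not missing[j + 1]
                  and abs(vv[j + 1] - vv[j]) < flat_tol):
                flat_samples = 2 if flat_samples == 0 else flat_samples + 1
                tail_end = j + 1
                j += 1
            else:
                break
        if not saw_missing and flat_samples < FLAT_MIN_RUN:
            continue  # normal varying velocity follows → not a blink
        raw.append((max(0, s - dilation), min(n - 1, tail_end + dilation)))

    if not raw:
        return []
    raw.sort()
    merged = [raw[0]]
    for s, e in raw[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return [BlinkSegment(s, e) for s, e in merged]


def _ar_design(context: np.ndarray, order: int, intercept: bool):
    rows = context.size - order
    cols = [context[order - 1 - k: order - 1 - k + rows] for k in range(order)]
    if intercept:
        cols.append(np.ones(rows))
    return np.column_stack(cols), context[order:]


def _ar_radius(coef: np.ndarray) -> float:
    roots = np.roots(np.concatenate(([1.0], -coef)))
    return float(np.abs(roots).max()) if roots.size else 0.0


def _fit_ar(context: np.ndarray, order: int):
    """Least-squares affine AR(order): coefficients (newest lag first)
    plus intercept.

    The affine fit reproduces linear trends and pure sinusoids exactly.
    When the fitted characteristic roots are explosive — which happens
    on short noisy context windows and would blow up over a gap — the
    fit is redone about the local level with the roots shrunk onto the
    unit circle, so extrapolation can grow at most linearly.
    """
    m = context.size
    if m < order + 2:
        return None, 0.0
    X, target = _ar_design(context, order, intercept=True)
    sol, *_ = np.linalg.lstsq(X, target, rcond=None)
    coef, c = sol[:order], float(sol[order])
    if _ar_radius(coef) <= 1.0 + 1e-9:
        return coef, c
    level = float(context.mean())
    X, target = _ar_design(context - level, order, intercept=False)
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    radius = _ar_radius(coef)
    if radius > 1.0 + 1e-9:
        roots = np.roots(np.concatenate(([1.0], -coef))) / radius
        coef = -np.poly(roots)[1:].real
    # express the level-reverting recursion in affine form
    return coef, level * (1.0 - float(coef.sum()))


def _extrapolate(context: np.ndarray, n_out: int, order: int) -> Optional[np.ndarray]:
    """Extend ``context`` forward by ``n_out`` samples with an AR fit."""
    finite = np.isfinite(context)
    if not finite.all():
        # keep only the trailing finite run adjacent to the gap
        last_bad = np.flatnonzero(~finite)
        context = context[last_bad[-1] + 1:]
    if context.size == 0:
        return None
    eff_order = min(order, context.size - 2)
    if eff_order < 1:
        return np.full(n_out, context[-1])
    coef, c = _fit_ar(context, eff_order)
    if coef is None or not np.all(np.isfinite(coef)) or not np.isfinite(c):
        return np.full(n_out, context[-1])
    hist = list(context[-eff_order:])
    out = np.empty(n_out)
    for i in range(n_out):
        nxt = float(np.dot(coef, hist[::-1])) + c
        if not np.isfinite(nxt):
            nxt = hist[-1]
        out[i] = nxt
        hist.pop(0)
        hist.append(nxt)
    return out


def fill_missing_ar(
    series: np.ndarray,
    segments: Sequence[BlinkSegment],
    context: int = AR_CONTEXT,
    order: int = AR_ORDER,
) -> np.ndarray:
    """Replace segment samples with averaged AR extrapolations.

    For each segment, an AR(``order``) model is fitted on the
    ``context`` samples preceding the gap and extrapolated forward, and
    another on the ``context`` samples following the gap and
    extrapolated backward; gap samples take the average of the two
    (or the single available one at trial edges).  Samples outside the
    segments are never modified.
    """
    out = np.array(series, dtype=float, copy=True)
    n = out.size
    for seg in sorted(segments, key=lambda s: s.start):
        s, e = seg.start, min(seg.end, n - 1)
        if s == 0 and e >= n - 1:
            raise ValueError("segment spans the entire series")
        fwd = None
        if s > 0:
            fwd = _extrapolate(out[max(0, s - context): s], e - s + 1, order)
        bwd = None
        if e < n - 1:
            rev = _extrapolate(out[e + 1: e + 1 + context][::-1], e - s + 1, order)
            bwd = rev[::-1] if rev is not None else None
        if fwd is not None and bwd is not None:
            out[s: e + 1] = 0.5 * (fwd + bwd)
        elif fwd is not None:
            out[s: e + 1] = fwd
        elif bwd is not None:
            out[s: e + 1] = bwd
        else:
            raise ValueError("segment has no valid context on either side")
    return out


def trial_is_valid(
    gaze: GazeRecording,
    blink_segments: Sequence[BlinkSegment],
    max_loss: float = MAX_LOSS_FRACTION,
) -> bool:
    """Keep a trial unless losses exceed ``max_loss`` (strictly)."""
    return _loss_fraction(gaze, blink_segments) <= max_loss


def _loss_fraction(
    gaze: GazeRecording, blink_segments: Sequence[BlinkSegment]
) -> float:
    n = gaze.n_samples
    lost = ~gaze.valid | ~np.isfinite(gaze.x) | ~np.isfinite(gaze.y)
    for seg in blink_segments:
        lost[seg.start: min(seg.end, n - 1) + 1] = True
    return float(lost.sum()) / n


@dataclass
class CleanTrial:
    """A preprocessed trial: gaze and stimulus in degrees, velocities,
    blink annotations and the keep/discard verdict."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    stim_x: np.ndarray
    stim_y: np.ndarray
    stim_vx: np.ndarray
    stim_vy: np.ndarray
    rate: float
    mode: str
    valid: bool
    blink_segments: List[BlinkSegment] = field(default_factory=list)
    loss_fraction: float = 0.0

    @property
    def n_blinks(self) -> int:
        return len(self.blink_segments)


def preprocess_trial(
    gaze: GazeRecording,
    stimulus: StimulusTrajectory,
    geometry: Optional[ScreenGeometry] = None,
    max_loss: float = MAX_LOSS_FRACTION,
) -> CleanTrial:
    """Run the full cleaning pipeline on one trial.

    ``gaze.units`` may be ``"deg"`` (used as-is) or ``"px"`` (converted
    with ``geometry``).  Blink segments and any other missing-data runs
    are AR-filled; the verdict reflects the pre-fill loss fraction.
    """
    if gaze.n_samples != stimulus.n_samples:
        raise ValueError("gaze and stimulus must share the same clock")
    if gaze.units == "px":
        if geometry is None:
            geometry = ScreenGeometry()
        gx, gy = screen_to_degrees(gaze.x, gaze.y, geometry)
    elif gaze.units == "deg":
        gx, gy = gaze.x.astype(float), gaze.y.astype(float)
    else:
        raise ValueError(f"unknown units {gaze.units!r}")

    rate = gaze.rate
    vy_raw = compute_velocity(gy, rate)
    segments = detect_blinks(vy_raw, gaze.valid)
    loss = _loss_fraction(gaze, segments)
    verdict = loss <= max_loss

    # fill blink segments plus any other missing runs (no dilation there)
    lost = ~gaze.valid | ~np.isfinite(gx) | ~np.isfinite(gy)
    for seg in segments:
        lost[seg.start: min(seg.end, gaze.n_samples - 1) + 1] = True
    fill_segs = [BlinkSegment(s, e) for s, e in _runs(lost)]
    if fill_segs and not lost.all():
        gx = fill_missing_ar(gx, fill_segs)
        gy = fill_missing_ar(gy, fill_segs)

    return CleanTrial(
        timestamps=gaze.timestamps.copy(),
        x=gx, y=gy,
        vx=compute_velocity(gx, rate),
        vy=compute_velocity(gy, rate),
        stim_x=stimulus.x.copy(), stim_y=stimulus.y.copy(),
        stim_vx=compute_velocity(stimulus.x, rate),
        stim_vy=compute_velocity(stimulus.y, rate),
        rate=rate, mode=stimulus.mode, valid=verdict,
        blink_segments=segments, loss_fraction=loss,
    )
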