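"""Parse raw gaze traces into saccades, fixations and blink spans.

Saccades are maximal runs where speed or |acceleration| exceeds the
velocity/acceleration thresholds (defaults 30 deg/s and 8000 deg/s^2).
Periods with no saccadic movement and no blink are fixations.
Differentiation uses central differences on the raw signal; an optional
3-sample moving average can be applied first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .io_types import FixationEvent, GazeTrace, SaccadeEvent

__all__ = [
    "ParserParams",
    "Kinematics",
    "estimate_kinematics",
    "detect_blinks",
    "detect_saccades",
    "detect_fixations",
    "parse_trace",
]


@dataclass
class ParserParams:
    velocity_threshold: float = 30.0       # deg/s
    acceleration_threshold: float = 8000.0  # deg/s^2
    min_saccade_duration_ms: float = 8.0
    min_fixation_duration_ms: float = 40.0
    blink_pad_ms: float = 50.0
    smooth: bool = False

    def __post_init__(self) -> None:
        for name in ("velocity_threshold", "acceleration_threshold",
                     "min_saccade_duration_ms", "min_fixation_duration_ms",
                     "blink_pad_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class Kinematics(NamedTuple):
    vx: np.ndarray      # deg/s
    vy: np.ndarray      # deg/s
    speed: np.ndarray   # deg/s
    accel: np.ndarray   # deg/s^2 (derivative of speed)


def _moving_average3(a: np.ndarray) -> np.ndarray:
    out = a.copy()
    out[1:-1] = (a[:-2] + a[1:-1] + a[2:]) / 3.0
    return out


def estimate_kinematics(trace: GazeTrace, smooth: bool = False) -> Kinematics:
    """Per-sample speed and acceleration by central differences.

    Endpoints use one-sided differences (``np.gradient``).  Samples inside
    or adjacent to invalid spans are NaN.
    """
    if trace.n < 3:
        raise ValueError("need at least 3 samples to estimate kinematics")
    if not trace.valid.any():
        warnings.warn(f"trace {trace.trial_id!r} is entirely invalid", stacklevel=2)
        nan = np.full(trace.n, np.nan)
        return Kinematics(nan, nan.copy(), nan.copy(), nan.copy())
    t_s = trace.t / 1000.0
    x = trace.x.copy()
    y = trace.y.copy()
    x[~trace.valid] = np.nan
    y[~trace.valid] = np.nan
    if smooth:
        x = _moving_average3(x)
        y = _moving_average3(y)
    vx = np.gradient(x, t_s)
    vy = np.gradient(y, t_s)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t_s)
    return Kinematics(vx, vy, speed, accel)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    if not mask.any():
        return []
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def _merge_spans(spans: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def detect_blinks(trace: GazeTrace, blink_pad_ms: float = 50.0) -> list[tuple[float, float]]:
    """Invalid spans, padded by ``blink_pad_ms`` each side and merged.

    Returns (start_ms, end_ms) pairs clipped to the trace span.
    """
    t0, t1 = float(trace.t[0]), float(trace.t[-1])
    spans = []
    for i0, i1 in _bool_runs(~trace.valid):
        lo = max(t0, trace.t[i0] - blink_pad_ms)
        hi = min(t1, trace.t[i1] + blink_pad_ms)
        spans.append((lo, hi))
    return _merge_spans(spans)


def _overlaps(a_lo: float, a_hi: float, spans: Sequence[tuple[float, float]]) -> bool:
    return any(lo <= a_hi and a_lo <= hi for lo, hi in spans)


def detect_saccades(trace: GazeTrace, params: ParserParams | None = None) -> list[SaccadeEvent]:
    """Threshold-based saccade parsing.

    A saccade is a maximal run where ``speed > velocity_threshold`` or
    ``|accel| > acceleration_threshold`` lasting at least
    ``min_saccade_duration_ms``.  Events overlapping a (padded) blink span
    are kept but flagged ``contains_blink``.
    """
    params = params or ParserParams()
    kin = estimate_kinematics(trace, smooth=params.smooth)
    with np.errstate(invalid="ignore"):
        mask = (kin.speed > params.velocity_threshold) | (
            np.abs(kin.accel) > params.acceleration_threshold
        )
    mask &= np.isfinite(kin.speed)
    blink_spans = detect_blinks(trace, params.blink_pad_ms)
    # samples inside blinks (and their differentiation neighbours) have NaN
    # kinematics and never trigger, so a blink interrupting a saccade splits
    # the run; bridge runs whose gap is entirely undefined kinematics
    runs = _bool_runs(mask)
    bridged: list[tuple[int, int]] = []
    for i0, i1 in runs:
        gap_ok = (
            bridged
            and trace.t[i0] - trace.t[bridged[-1][1]] <= 300.0
            and bool(np.isnan(kin.speed[bridged[-1][1] + 1: i0]).all())
        )
        if gap_ok:
            bridged[-1] = (bridged[-1][0], i1)
        else:
            bridged.append((i0, i1))
    events: list[SaccadeEvent] = []
    ordinal = 0
    for k, (i0, i1) in enumerate(bridged):
        onset = float(trace.t[i0])
        offset = float(trace.t[i1])
        if offset - onset < params.min_saccade_duration_ms:
            continue
        # extend endpoints by up to 2 samples (not crossing neighbouring
        # runs) so sub-threshold displacement tails count toward amplitude
        lo = max(i0 - 2, 0 if k == 0 else bridged[k - 1][1] + 1)
        hi = min(i1 + 2, trace.n - 1 if k == len(bridged) - 1 else bridged[k + 1][0] - 1)
        seg = slice(lo, hi + 1)
        v = trace.valid[seg]
        xs = trace.x[seg][v]
        ys = trace.y[seg][v]
        if xs.size:
            start_xy = (float(xs[0]), float(ys[0]))
            end_xy = (float(xs[-1]), float(ys[-1]))
        else:  # fully inside a blink
            start_xy = end_xy = (np.nan, np.nan)
        amplitude = float(np.hypot(end_xy[0] - start_xy[0], end_xy[1] - start_xy[1]))
        if not np.isfinite(amplitude):
            amplitude = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pv = float(np.nanmax(kin.speed[seg]))
        if not np.isfinite(pv):
            pv = 0.0
        ordinal += 1
        events.append(SaccadeEvent(
            onset_ms=onset,
            offset_ms=offset,
            start_xy=start_xy,
            end_xy=end_xy,
            amplitude=amplitude,
            peak_velocity=pv,
            contains_blink=_overlaps(onset, offset, blink_spans),
            ordinal=ordinal,
        ))
    return events


def detect_fixations(
    trace: GazeTrace,
    saccades: Sequence[SaccadeEvent],
    blinks: Sequence[tuple[float, float]],
    params: ParserParams | None = None,
) -> list[FixationEvent]:
    """Complement of saccade and blink spans, kept if long enough.

    ``mean_xy`` is taken over valid samples inside the fixation window.
    """
    params = params or ParserParams()
    t0, t1 = float(trace.t[0]), float(trace.t[-1])
    occupied = _merge_spans(
        [(s.onset_ms, s.offset_ms) for s in saccades] + [tuple(b) for b in blinks]
    )
    free: list[tuple[float, float]] = []
    cursor = t0
    for lo, hi in occupied:
        if lo > cursor:
            free.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < t1:
        free.append((cursor, t1))
    fixations: list[FixationEvent] = []
    for lo, hi in free:
        if hi - lo < params.min_fixation_duration_ms:
            continue
        sel = (trace.t >= lo) & (trace.t <= hi) & trace.valid
        if sel.any():
            mean_xy = (float(trace.x[sel].mean()), float(trace.y[sel].mean()))
        else:
            mean_xy = (np.nan, np.nan)
        fixations.append(FixationEvent(onset_ms=lo, offset_ms=hi, mean_xy=mean_xy))
    return fixations


def parse_trace(trace: GazeTrace, params: ParserParams | None = None):
    """Full parse: (saccades, fixations, blink spans)."""
    params = params or ParserParams()
    blinks = detect_blinks(trace, params.blink_pad_ms)
    saccades = detect_saccades(trace, params)
    fixations = detect_fixations(trace, saccades, blinks, params)
    return saccades, fixations, blinks
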