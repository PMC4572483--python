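"""Smooth-pursuit analysis: instantaneous velocity gain with exclusion
windows and tail trimming, plus pursuit saccade counts.

Gain is the signed along-axis eye velocity divided by target velocity,
computed per sample.  Samples inside saccades, blinks or invalid spans
(padded +-50 ms) are excluded, ratios are trimmed to [-1, +2], and
near-turnaround samples (|target velocity| below a small floor) are
dropped because the ratio is unbounded there; a floor of 0 reproduces the
literal exclusion-free procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .event_detection import estimate_kinematics
from .io_types import GazeTrace, SaccadeEvent, TrialRecord

__all__ = [
    "PursuitTrialResult",
    "target_kinematics",
    "exclusion_mask",
    "instantaneous_gain",
    "trim_gain",
    "count_pursuit_saccades",
    "analyze_pursuit_trial",
]


@dataclass
class PursuitTrialResult:
    trial_id: str
    axis: str
    gain_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_gain: float = math.nan
    n_saccades: int = 0
    excluded_fraction: float = 0.0


def target_kinematics(trial: TrialRecord, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic target position (deg) and velocity (deg/s) at ``t_ms``.

    The target starts at centre and follows ``A * sin(2*pi*f*t)`` along
    the trial's pursuit axis.
    """
    if trial.task != "pursuit":
        raise ValueError(f"trial {trial.trial_id!r} is not a pursuit trial")
    a = trial.pursuit_amplitude_deg
    f = trial.pursuit_freq_hz
    t_s = np.asarray(t_ms, dtype=float) / 1000.0
    pos = a * np.sin(2.0 * np.pi * f * t_s)
    vel = a * 2.0 * np.pi * f * np.cos(2.0 * np.pi * f * t_s)
    return pos, vel


def exclusion_mask(
    trace: GazeTrace,
    saccades: Sequence[SaccadeEvent],
    blinks: Sequence[tuple[float, float]],
    pad_ms: float = 50.0,
) -> np.ndarray:
    """Per-sample keep mask: True where the sample is retained.

    Samples inside any saccade, blink span or invalid run, padded by
    ``pad_ms`` either side, are dropped.
    """
    keep = trace.valid.copy()
    spans = [(s.onset_ms - pad_ms, s.offset_ms + pad_ms) for s in saccades]
    spans += [(lo - pad_ms, hi + pad_ms) for lo, hi in blinks]
    # pad raw invalid runs too, in case the blink spans were built unpadded
    inv = np.flatnonzero(~trace.valid)
    if inv.size:
        run_starts = np.concatenate(([inv[0]], inv[np.flatnonzero(np.diff(inv) > 1) + 1]))
        run_ends = np.concatenate((inv[np.flatnonzero(np.diff(inv) > 1)], [inv[-1]]))
        spans += [
            (trace.t[i0] - pad_ms, trace.t[i1] + pad_ms)
            for i0, i1 in zip(run_starts, run_ends)
        ]
    for lo, hi in spans:
        keep &= ~((trace.t >= lo) & (trace.t <= hi))
    return keep


def instantaneous_gain(
    trace: GazeTrace,
    trial: TrialRecord,
    mask: np.ndarray,
    min_target_speed: float = 2.0,
    smooth: bool = False,
) -> np.ndarray:
    """Signed along-axis eye velocity / target velocity per retained sample.

    Samples where |target velocity| < ``min_target_speed`` are dropped in
    addition to the supplied mask.
    """
    kin = estimate_kinematics(trace, smooth=smooth)
    eye_v = kin.vx if trial.pursuit_axis == "horizontal" else kin.vy
    _, target_v = target_kinematics(trial, trace.t)
    sel = np.asarray(mask, dtype=bool) & np.isfinite(eye_v)
    if min_target_speed > 0:
        sel &= np.abs(target_v) >= min_target_speed
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = eye_v[sel] / target_v[sel]
    return gain[np.isfinite(gain)]


def trim_gain(
    gain_samples: np.ndarray, low: float = -1.0, high: float = 2.0
) -> tuple[np.ndarray, float]:
    """Cut the tails of the gain distribution at ``[low, high]``.

    Returns ``(retained, trimmed_fraction)``.
    """
    g = np.asarray(gain_samples, dtype=float)
    if g.size == 0:
        return g, 0.0
    keep = (g >= low) & (g <= high)
    return g[keep], float(1.0 - keep.mean())


def count_pursuit_saccades(
    saccades: Sequence[SaccadeEvent], min_amplitude_deg: float = 2.0
) -> int:
    """Blink-free saccades with amplitude strictly above 2 deg."""
    return sum(
        1
        for s in saccades
        if s.amplitude > min_amplitude_deg and not s.contains_blink
    )


def analyze_pursuit_trial(
    trace: GazeTrace,
    trial: TrialRecord,
    saccades: Sequence[SaccadeEvent],
    blinks: Sequence[tuple[float, float]],
    pad_ms: float = 50.0,
    min_target_speed: float = 2.0,
    trim_low: float = -1.0,
    trim_high: float = 2.0,
) -> PursuitTrialResult:
    """Full per-trial pursuit summary (gain after exclusions + trim,
    saccade count, excluded fraction)."""
    keep = exclusion_mask(trace, saccades, blinks, pad_ms=pad_ms)
    excluded_fraction = float(1.0 - keep.mean())
    gain = instantaneous_gain(trace, trial, keep, min_target_speed=min_target_speed)
    retained, _ = trim_gain(gain, low=trim_low, high=trim_high)
    return PursuitTrialResult(
        trial_id=trial.trial_id,
        axis=trial.pursuit_axis,
        gain_samples=retained,
        mean_gain=float(retained.mean()) if retained.size else math.nan,
        n_saccades=count_pursuit_saccades(saccades),
        excluded_fraction=excluded_fraction,
    )
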