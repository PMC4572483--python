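"""Saccade-task analysis: time to first target fixation, main-saccade
selection, amplitude error, latency with square-root transform and +-2 SD
trimming, saccade counts and the gap/overlap contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_types import FixationEvent, SaccadeEvent, TrialRecord

__all__ = [
    "MainSaccadeResult",
    "time_to_first_target_fixation",
    "identify_main_saccade",
    "saccade_latency",
    "amplitude_error",
    "sqrt_transform_trim",
    "count_trial_saccades",
    "removal_rate",
    "gap_overlap_effect",
]


@dataclass
class MainSaccadeResult:
    """Outcome of the main-saccade selection algorithm for one trial.

    ``status`` is ``selected`` (a survivor with within-trial ordinal <= 5),
    ``discarded`` (first survivor was the sixth parsed saccade or later) or
    ``no_candidate`` (every saccade was removed by the filters).
    """

    trial_id: str
    status: str
    saccade: SaccadeEvent | None = None
    latency_ms: float | None = None
    amplitude_error_deg: float | None = None  # positive = overshoot
    peak_velocity: float | None = None


def time_to_first_target_fixation(
    trial: TrialRecord,
    fixations: Sequence[FixationEvent],
    radius_deg: float = 2.5,
    response_window_ms: float = 5000.0,
) -> float | None:
    """Time from target onset to the first fixation within ``radius_deg``.

    The fixation's mean position is used for the distance test.  A
    qualifying fixation already ongoing at target onset yields 0 ms
    (clamped, never negative).  Returns ``None`` if no fixation qualifies
    within the response window.
    """
    t_on = trial.target_onset_ms
    tx, ty = trial.target_location
    for fix in sorted(fixations, key=lambda f: f.onset_ms):
        if fix.offset_ms <= t_on:
            continue
        if fix.onset_ms > t_on + response_window_ms:
            break
        mx, my = fix.mean_xy
        if not (math.isfinite(mx) and math.isfinite(my)):
            continue
        if math.hypot(mx - tx, my - ty) <= radius_deg:
            return max(0.0, fix.onset_ms - t_on)
    return None


def _direction_error_deg(
    saccade: SaccadeEvent, fixation_xy: tuple[float, float], target_xy: tuple[float, float]
) -> float:
    """Absolute angle between the saccade displacement and the
    fixation-point -> target vector, in degrees."""
    dx, dy = saccade.displacement
    rx, ry = target_xy[0] - fixation_xy[0], target_xy[1] - fixation_xy[1]
    n1 = math.hypot(dx, dy)
    n2 = math.hypot(rx, ry)
    if n1 == 0 or n2 == 0:
        return 180.0
    cosang = max(-1.0, min(1.0, (dx * rx + dy * ry) / (n1 * n2)))
    return math.degrees(math.acos(cosang))


def identify_main_saccade(
    trial: TrialRecord,
    saccades: Sequence[SaccadeEvent],
    fixation_xy: tuple[float, float] = (0.0, 0.0),
    max_start_dist_deg: float = 2.5,
    max_direction_error_deg: float = 45.0,
    max_ordinal: int = 5,
) -> MainSaccadeResult:
    """Select the first major saccade towards the target.

    Saccades that contain a blink, start before target onset, start more
    than ``max_start_dist_deg`` from the central fixation point, or whose
    direction deviates from the fixation-point->target vector by more than
    ``max_direction_error_deg`` are removed; the first survivor is kept.
    If the survivor's within-trial ordinal exceeds ``max_ordinal`` the
    trial is discarded.  Ordinals count every parsed saccade in the trial
    from trial start, including ones the filters remove.
    """
    survivors = []
    for s in sorted(saccades, key=lambda s: s.onset_ms):
        if s.contains_blink:
            continue
        if s.onset_ms < trial.target_onset_ms:
            continue
        if math.hypot(s.start_xy[0] - fixation_xy[0], s.start_xy[1] - fixation_xy[1]) > max_start_dist_deg:
            continue
        if _direction_error_deg(s, fixation_xy, trial.target_location) > max_direction_error_deg:
            continue
        survivors.append(s)
    if not survivors:
        return MainSaccadeResult(trial_id=trial.trial_id, status="no_candidate")
    main = survivors[0]
    if main.ordinal > max_ordinal:
        return MainSaccadeResult(trial_id=trial.trial_id, status="discarded", saccade=main)
    return MainSaccadeResult(
        trial_id=trial.trial_id,
        status="selected",
        saccade=main,
        latency_ms=main.onset_ms - trial.target_onset_ms,
        amplitude_error_deg=main.amplitude - trial.eccentricity,
        peak_velocity=main.peak_velocity,
    )


def saccade_latency(result: MainSaccadeResult) -> float | None:
    """Target onset to main-saccade onset, ms; ``None`` unless selected."""
    if result.status != "selected":
        return None
    return result.latency_ms


def amplitude_error(result: MainSaccadeResult, trial: TrialRecord) -> float | None:
    """Main-saccade amplitude minus target eccentricity (negative =
    hypometric, positive = hypermetric); ``None`` unless selected."""
    if result.status != "selected":
        return None
    return result.saccade.amplitude - trial.eccentricity


def sqrt_transform_trim(
    values: Sequence[float],
    groups: Sequence[str],
    z: float = 2.0,
    min_group_n: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Square-root transform then drop |z| > ``z`` outliers per group.

    Returns ``(transformed, keep)`` where ``transformed`` is sqrt(values)
    (NaN preserved) and ``keep`` marks retained entries.  Group SD uses
    the n-1 denominator; a zero-SD group removes nothing.  Groups with
    fewer than ``min_group_n`` finite observations skip trimming with a
    warning.  NaN inputs are never retained.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    if np.any(values[np.isfinite(values)] < 0):
        raise ValueError("values must be non-negative for the square-root transform")
    transformed = np.sqrt(values)
    keep = np.isfinite(transformed)
    for g in pd.unique(groups):
        sel = (groups == g) & np.isfinite(transformed)
        n = int(sel.sum())
        if n < min_group_n:
            warnings.warn(
                f"group {g!r} has only {n} observation(s); trim skipped", stacklevel=2
            )
            continue
        gv = transformed[sel]
        sd = gv.std(ddof=1)
        if sd == 0:
            continue
        zscores = (gv - gv.mean()) / sd
        bad = np.abs(zscores) > z
        idx = np.flatnonzero(sel)
        keep[idx[bad]] = False
    return transformed, keep


def count_trial_saccades(
    trial: TrialRecord,
    saccades: Sequence[SaccadeEvent],
    min_amplitude_deg: float = 2.0,
) -> int:
    """Blink-free saccades above ``min_amplitude_deg`` starting at or
    after target onset."""
    return sum(
        1
        for s in saccades
        if s.onset_ms >= trial.target_onset_ms
        and not s.contains_blink
        and s.amplitude > min_amplitude_deg
    )


def removal_rate(results: Sequence[MainSaccadeResult]) -> float:
    """Proportion of trials removed (discarded or no candidate)."""
    if not results:
        raise ValueError("no trial results supplied")
    removed = sum(1 for r in results if r.status != "selected")
    return removed / len(results)


def gap_overlap_effect(
    rows: pd.DataFrame,
    value_col: str = "value",
    transform: str = "sqrt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant overlap minus gap contrast on the analysis scale.

    ``rows`` needs columns ``participant_id``, ``group``, ``condition``
    and ``value_col``.  Participants missing either condition are excluded
    with a warning.  Returns ``(per_participant, per_group)`` frames; the
    group frame has mean/SD/SEM/n of the contrast.
    """
    df = rows.dropna(subset=[value_col]).copy()
    if transform == "sqrt":
        df[value_col] = np.sqrt(df[value_col])
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    means = (
        df.groupby(["participant_id", "group", "condition"])[value_col]
        .mean()
        .unstack("condition")
    )
    for cond in ("gap", "overlap"):
        if cond not in means.columns:
            means[cond] = np.nan
    incomplete = means["gap"].isna() | means["overlap"].isna()
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} participant(s) missing a condition; excluded",
            stacklevel=2,
        )
        means = means[~incomplete]
    per_participant = means.reset_index()
    per_participant["contrast"] = per_participant["overlap"] - per_participant["gap"]
    per_group = (
        per_participant.groupby("group")["contrast"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    per_group["sem"] = per_group["sd"] / np.sqrt(per_group["n"])
    return per_participant, per_group
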