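"""Fixation-stability metrics: square wave jerks, large intrusive
saccades and the longest period of fixation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io_types import SaccadeEvent

__all__ = [
    "SWJEvent",
    "count_square_wave_jerks",
    "count_large_intrusive_saccades",
    "longest_fixation_period",
]


@dataclass
class SWJEvent:
    """A matched pair of small opposing saccades (square wave jerk)."""

    first_saccade: SaccadeEvent
    second_saccade: SaccadeEvent
    inter_saccade_interval_ms: float
    amplitude_difference_deg: float


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _moves_away(s: SaccadeEvent, target_xy: tuple[float, float]) -> bool:
    return _dist(s.end_xy, target_xy) > _dist(s.start_xy, target_xy)


def _moves_toward(s: SaccadeEvent, target_xy: tuple[float, float]) -> bool:
    return _dist(s.end_xy, target_xy) < _dist(s.start_xy, target_xy)


def count_square_wave_jerks(
    saccades: Sequence[SaccadeEvent],
    target_xy: tuple[float, float] = (0.0, 0.0),
    max_amplitude_deg: float = 2.0,
    max_interval_ms: float = 300.0,
    max_amplitude_diff_deg: float = 0.75,
    interval_anchor: str = "offset_to_onset",
) -> tuple[int, list[SWJEvent]]:
    """Count square wave jerks in a fixation trial.

    A qualifying pair is: a saccade of amplitude below
    ``max_amplitude_deg`` taking gaze away from the target, followed
    within ``max_interval_ms`` by another sub-``max_amplitude_deg``
    saccade of similar amplitude (difference below
    ``max_amplitude_diff_deg``) taking gaze back towards it.  Away/toward
    is judged by end-point vs start-point distance to the target.
    Pairing is greedy left-to-right and each saccade participates in at
    most one pair.
    """
    if interval_anchor not in ("offset_to_onset", "onset_to_onset"):
        raise ValueError(f"unknown interval anchor {interval_anchor!r}")
    saccades = sorted(saccades, key=lambda s: s.onset_ms)
    used = [False] * len(saccades)
    pairs: list[SWJEvent] = []
    for i, first in enumerate(saccades):
        if used[i]:
            continue
        if first.amplitude >= max_amplitude_deg:
            continue
        if not _moves_away(first, target_xy):
            continue
        anchor = first.offset_ms if interval_anchor == "offset_to_onset" else first.onset_ms
        for j in range(i + 1, len(saccades)):
            if used[j]:
                continue
            second = saccades[j]
            interval = second.onset_ms - anchor
            if interval >= max_interval_ms:
                break  # saccades are time ordered; later ones only worse
            if second.amplitude >= max_amplitude_deg:
                continue
            if abs(second.amplitude - first.amplitude) >= max_amplitude_diff_deg:
                continue
            if not _moves_toward(second, target_xy):
                continue
            used[i] = used[j] = True
            pairs.append(SWJEvent(
                first_saccade=first,
                second_saccade=second,
                inter_saccade_interval_ms=interval,
                amplitude_difference_deg=abs(second.amplitude - first.amplitude),
            ))
            break
    return len(pairs), pairs


def count_large_intrusive_saccades(
    saccades: Sequence[SaccadeEvent],
    min_amplitude_deg: float = 2.0,
) -> int:
    """Blink-free saccades with amplitude strictly greater than 2 deg."""
    return sum(
        1
        for s in saccades
        if s.amplitude > min_amplitude_deg and not s.contains_blink
    )


def longest_fixation_period(
    trials: Sequence[tuple[Sequence[SaccadeEvent], tuple[float, float]]],
) -> float:
    """Maximum time between saccades across scored trials, in ms.

    Each trial is given as ``(saccades, (trial_start_ms, trial_end_ms))``;
    trial boundaries cap the interval.  Raises ``ValueError`` if no trials
    are supplied.
    """
    if not trials:
        raise ValueError("longest_fixation_period requires at least one trial")
    best = 0.0
    for saccades, (t0, t1) in trials:
        if t1 <= t0:
            raise ValueError(f"empty trial span ({t0}, {t1})")
        saccades = sorted(saccades, key=lambda s: s.onset_ms)
        # gaps: trial start -> first onset, offset_i -> onset_{i+1}, last offset -> trial end
        gap_starts = [t0] + [s.offset_ms for s in saccades]
        gap_ends = [s.onset_ms for s in saccades] + [t1]
        gaps = [max(0.0, end - start) for start, end in zip(gap_starts, gap_ends)]
        best = max(best, max(gaps))
    return best
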