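"""Task schedule generation.

Default schedule: fixation (1 practice + 3 scored, 10 s each); saccade
task of 4 blocks x 10 trials with every target location used once per
block and the gap/overlap condition alternated in an ABBA block design;
pursuit (2 practice + 3 horizontal + 3 vertical scored trials, 10 s
sinusoid at 0.25 Hz, 10 deg half-range).  In gap trials target onset is
200 ms after central fixation offset; in overlap trials 200 ms before.
"""

from __future__ import annotations

import math

import numpy as np

from ..io_types import ScheduleConfig, TrialRecord

__all__ = ["build_task_schedule"]


def build_task_schedule(
    config: ScheduleConfig | None = None,
    seed: int | np.random.Generator | None = 0,
) -> list[TrialRecord]:
    """Generate the full trial list for one session.

    ``seed`` only affects the within-block ordering of saccade targets.
    """
    cfg = config or ScheduleConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[TrialRecord] = []

    # --- fixation ---
    for i in range(cfg.fixation_practice_trials):
        trials.append(TrialRecord(
            trial_id=f"fix-p{i + 1}", task="fixation",
            target_location=(0.0, 0.0),
            duration_ms=cfg.fixation_duration_ms, practice=True,
        ))
    for i in range(cfg.fixation_scored_trials):
        trials.append(TrialRecord(
            trial_id=f"fix-{i + 1}", task="fixation",
            target_location=(0.0, 0.0),
            duration_ms=cfg.fixation_duration_ms,
        ))

    # --- saccade task, ABBA condition blocks ---
    locations = cfg.target_locations
    base = ["gap", "overlap"]
    block_conditions = []
    while len(block_conditions) < cfg.saccade_blocks:
        block_conditions += [base[0], base[1], base[1], base[0]]  # ABBA
    block_conditions = block_conditions[: cfg.saccade_blocks]
    fix_off = cfg.central_fixation_duration_ms
    for b, condition in enumerate(block_conditions, start=1):
        order = rng.permutation(len(locations))
        for k, loc_i in enumerate(order, start=1):
            tx, ty = locations[loc_i]
            if condition == "gap":
                target_onset = fix_off + cfg.gap_ms
            else:
                target_onset = fix_off - cfg.overlap_ms
            trials.append(TrialRecord(
                trial_id=f"sac-b{b}-{k:02d}", task="saccade", condition=condition,
                target_location=(tx, ty), eccentricity=math.hypot(tx, ty),
                fixation_offset_ms=fix_off, target_onset_ms=target_onset,
                duration_ms=target_onset + cfg.response_window_ms,
            ))

    # --- pursuit ---
    axes = ("horizontal", "vertical")
    for i in range(cfg.pursuit_practice_trials):
        trials.append(_pursuit_trial(cfg, f"pur-p{i + 1}", axes[i % 2], practice=True))
    for i in range(2 * cfg.pursuit_scored_per_axis):
        trials.append(_pursuit_trial(cfg, f"pur-{i + 1}", axes[i % 2]))
    return trials


def _pursuit_trial(cfg: ScheduleConfig, trial_id: str, axis: str,
                   practice: bool = False) -> TrialRecord:
    return TrialRecord(
        trial_id=trial_id, task="pursuit", pursuit_axis=axis,
        pursuit_freq_hz=cfg.pursuit_freq_hz,
        pursuit_amplitude_deg=cfg.pursuit_amplitude_deg,
        duration_ms=cfg.pursuit_duration_ms, practice=practice,
    )
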