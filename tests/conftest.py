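import math

import numpy as np
import pytest

from oculokit.io_types import GazeTrace, SaccadeEvent, TrialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(x, y=None, trial_id="trial", valid=None, rate_hz=250.0):
    """Build a GazeTrace from position arrays on a uniform 250 Hz grid."""
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    t = np.arange(x.size) * (1000.0 / rate_hz)
    if valid is None:
        valid = np.ones(x.size, dtype=bool)
    return GazeTrace(trial_id=trial_id, t=t, x=x, y=np.asarray(y, float),
                     valid=np.asarray(valid, bool), rate_hz=rate_hz)


def make_saccade(onset, offset, start, end, contains_blink=False, ordinal=1,
                 peak_velocity=200.0):
    start = tuple(map(float, start))
    end = tuple(map(float, end))
    return SaccadeEvent(
        onset_ms=float(onset), offset_ms=float(offset),
        start_xy=start, end_xy=end,
        amplitude=math.hypot(end[0] - start[0], end[1] - start[1]),
        peak_velocity=peak_velocity, contains_blink=contains_blink,
        ordinal=ordinal,
    )


def make_saccade_trial(target=(10.0, 0.0), condition="gap", trial_id="sac-1"):
    fix_off = 500.0
    onset = fix_off + 200.0 if condition == "gap" else fix_off - 200.0
    return TrialRecord(
        trial_id=trial_id, task="saccade", condition=condition,
        target_location=target, eccentricity=math.hypot(*target),
        fixation_offset_ms=fix_off, target_onset_ms=onset,
        duration_ms=onset + 5000.0,
    )


def make_pursuit_trial(axis="horizontal", trial_id="pur-1", freq=0.25, amp=10.0,
                       duration=10_000.0):
    return TrialRecord(
        trial_id=trial_id, task="pursuit", pursuit_axis=axis,
        pursuit_freq_hz=freq, pursuit_amplitude_deg=amp, duration_ms=duration,
    )


def make_fixation_trial(trial_id="fix-1", duration=10_000.0, practice=False):
    return TrialRecord(
        trial_id=trial_id, task="fixation", target_location=(0.0, 0.0),
        duration_ms=duration, practice=practice,
    )
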