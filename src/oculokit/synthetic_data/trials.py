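"""Per-trial gaze-trace simulation with ground truth.

Traces are sampled at the nominal rate with band-limited Gaussian
positional noise (white noise smoothed over ~3 samples and rescaled to
the requested SD) so that velocity thresholds are not tripped by noise
alone.  Saccades are injected as main-sequence waveforms; blinks mark
samples invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..io_types import GazeTrace, TrialRecord
from .profiles import CohortProfile
from .waveform import SaccadeWaveform

__all__ = [
    "GroundTruth",
    "simulate_fixation_trial",
    "simulate_saccade_trial",
    "simulate_pursuit_trial",
    "simulate_trial",
]

_NOISE_SIGMA_SAMPLES = 3.0


@dataclass
class GroundTruth:
    """What was injected into one simulated trial."""

    trial_id: str
    injected_saccades: list[dict] = field(default_factory=list)  # type/onset/amplitude
    n_swj: int = 0
    n_intrusions: int = 0
    n_blinks: int = 0
    true_latency_ms: float | None = None
    intended_main: dict | None = None
    true_gain: float | None = None
    n_catchup: int = 0


def _time_grid(duration_ms: float, rate_hz: float) -> np.ndarray:
    dt = 1000.0 / rate_hz
    n = int(round(duration_ms / dt)) + 1
    return np.arange(n) * dt


def _band_limited_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    f = gaussian_filter1d(w, _NOISE_SIGMA_SAMPLES, mode="reflect")
    s = f.std()
    return f * (sd / s) if s > 0 else f


def _inject_saccade(
    t: np.ndarray, x: np.ndarray, y: np.ndarray,
    onset_ms: float, amplitude: float, direction: tuple[float, float],
    velocity_scale: float = 1.0,
) -> SaccadeWaveform:
    """Add a saccade displacement profile in place; returns its waveform."""
    wf = SaccadeWaveform(amplitude=amplitude, velocity_scale=velocity_scale)
    rel = t - onset_ms
    disp = np.where(rel <= 0, 0.0, np.where(rel >= wf.duration_ms, amplitude,
                                            wf.displacement(rel)))
    dx, dy = direction
    x += disp * dx
    y += disp * dy
    return wf


def _unit(angle_rad: float) -> tuple[float, float]:
    return (math.cos(angle_rad), math.sin(angle_rad))


def _allocate_slots(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    length: float,
    occupied: list[tuple[float, float]],
    tries: int = 60,
) -> list[float]:
    """Greedy non-overlapping placement of ``n`` event onsets."""
    placed: list[float] = []
    if hi - length <= lo:
        return placed
    for _ in range(n):
        for _ in range(tries):
            onset = rng.uniform(lo, hi - length)
            span = (onset, onset + length)
            if all(span[1] < s0 or span[0] > s1 for s0, s1 in occupied):
                occupied.append(span)
                placed.append(onset)
                break
    return sorted(placed)


def _add_blinks(
    rng: np.random.Generator,
    t: np.ndarray,
    valid: np.ndarray,
    rate_per_10s: float,
    occupied: list[tuple[float, float]],
) -> int:
    duration = t[-1] - t[0]
    lam = rate_per_10s * duration / 10_000.0
    n = rng.poisson(lam)
    onsets = _allocate_slots(rng, n, t[0] + 100.0, t[-1] - 100.0, 500.0, occupied)
    for onset in onsets:
        blen = rng.uniform(100.0, 300.0)
        valid[(t >= onset) & (t <= onset + blen)] = False
    return len(onsets)


def simulate_fixation_trial(
    profile: CohortProfile,
    trial: TrialRecord,
    rng: np.random.Generator,
    rate_hz: float = 250.0,
) -> tuple[GazeTrace, GroundTruth]:
    """Fixation at the target with Poisson-count square wave jerks,
    Poisson-count large intrusions (>2 deg, slow drift back) and blinks."""
    t = _time_grid(trial.duration_ms, rate_hz)
    tx, ty = trial.target_location
    x = np.full(t.size, tx)
    y = np.full(t.size, ty)
    valid = np.ones(t.size, dtype=bool)
    gt = GroundTruth(trial_id=trial.trial_id)
    occupied: list[tuple[float, float]] = []

    # square wave jerks: small outward saccade, return within 300 ms
    swj_onsets = _allocate_slots(
        rng, rng.poisson(profile.swj_rate), 300.0, t[-1] - 1500.0, 1400.0, occupied
    )
    for onset in swj_onsets:
        amp_out = rng.uniform(1.2, 1.9)
        diff = rng.uniform(-0.45, 0.45)
        amp_back = float(np.clip(amp_out + diff, 1.1, 1.95))
        ang = rng.uniform(0.0, 2.0 * math.pi)
        d_out = _unit(ang)
        wf_out = _inject_saccade(t, x, y, onset, amp_out, d_out, profile.velocity_scale)
        back_onset = onset + wf_out.duration_ms + rng.uniform(60.0, 200.0)
        wf_back = _inject_saccade(
            t, x, y, back_onset, amp_back, (-d_out[0], -d_out[1]), profile.velocity_scale
        )
        # slowly absorb the residual offset so position returns to target
        residual = amp_out - amp_back
        drift_start = back_onset + wf_back.duration_ms + 100.0
        drift = np.clip((t - drift_start) / 400.0, 0.0, 1.0) * residual
        x -= drift * d_out[0]
        y -= drift * d_out[1]
        gt.injected_saccades.append({"type": "swj_out", "onset_ms": onset, "amplitude": amp_out})
        gt.injected_saccades.append({"type": "swj_back", "onset_ms": back_onset, "amplitude": amp_back})
    gt.n_swj = len(swj_onsets)

    # large intrusive saccades: > 2 deg outward, slow smooth return
    n_int = rng.poisson(profile.intrusion_rate)
    placed = _allocate_slots(rng, n_int, 300.0, t[-1] - 2200.0, 2000.0, occupied)
    for onset in placed:
        amp = rng.uniform(2.5, 5.0)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        d = _unit(ang)
        wf = _inject_saccade(t, x, y, onset, amp, d, profile.velocity_scale)
        dwell = rng.uniform(300.0, 600.0)
        ret_start = onset + wf.duration_ms + dwell
        ret_dur = rng.uniform(600.0, 900.0)
        drift = np.clip((t - ret_start) / ret_dur, 0.0, 1.0) * amp
        x -= drift * d[0]
        y -= drift * d[1]
        gt.injected_saccades.append({"type": "intrusion", "onset_ms": onset, "amplitude": amp})
    gt.n_intrusions = len(placed)

    gt.n_blinks = _add_blinks(rng, t, valid, profile.blink_rate, occupied)
    x += _band_limited_noise(rng, t.size, profile.noise_sd_deg)
    y += _band_limited_noise(rng, t.size, profile.noise_sd_deg)
    trace = GazeTrace(trial_id=trial.trial_id, t=t, x=x, y=y, valid=valid, rate_hz=rate_hz)
    return trace, gt


def simulate_saccade_trial(
    profile: CohortProfile,
    trial: TrialRecord,
    rng: np.random.Generator,
    rate_hz: float = 250.0,
) -> tuple[GazeTrace, GroundTruth]:
    """Gap/overlap saccade trial: log-normal latency (+ penalty in the
    overlap condition), a main saccade of amplitude gain * eccentricity,
    then corrective saccades until gaze is within 1.5 deg of the target."""
    t = _time_grid(trial.duration_ms, rate_hz)
    x = np.zeros(t.size)
    y = np.zeros(t.size)
    valid = np.ones(t.size, dtype=bool)
    gt = GroundTruth(trial_id=trial.trial_id, true_gain=profile.saccadic_gain)
    occupied: list[tuple[float, float]] = []

    tx, ty = trial.target_location
    ecc = trial.eccentricity
    latency = rng.lognormal(math.log(profile.latency_median_ms), profile.latency_sigma)
    if trial.condition == "overlap":
        latency += profile.overlap_penalty_ms
    latency = float(np.clip(latency, 80.0, trial.duration_ms - trial.target_onset_ms - 400.0))
    gt.true_latency_ms = latency
    onset = trial.target_onset_ms + latency

    angle_to_target = math.atan2(ty, tx)
    wrong = rng.random() < profile.wrong_direction_prob
    if wrong:
        ang = angle_to_target + math.pi + rng.uniform(-0.5, 0.5)
    else:
        ang = angle_to_target + rng.normal(0.0, 0.04)
    amp = float(max(0.5, profile.saccadic_gain * ecc
                    * (1.0 + rng.normal(0.0, profile.amplitude_noise_frac))))
    if wrong:
        amp = min(amp, 5.0)
    wf = _inject_saccade(t, x, y, onset, amp, _unit(ang), profile.velocity_scale)
    occupied.append((onset, onset + wf.duration_ms))
    pos = np.array([amp * math.cos(ang), amp * math.sin(ang)])
    gt.intended_main = {"onset_ms": onset, "amplitude": amp, "wrong_direction": wrong}
    gt.injected_saccades.append({"type": "main", "onset_ms": onset, "amplitude": amp})

    # corrective saccades bridge the residual error
    cursor = onset + wf.duration_ms
    target = np.array([tx, ty])
    for _ in range(8):
        err = target - pos
        dist = float(np.hypot(*err))
        if dist <= 1.5:
            break
        c_onset = cursor + rng.uniform(150.0, 320.0)
        c_amp = float(max(0.3, dist * rng.uniform(0.8, 1.0)))
        c_ang = math.atan2(err[1], err[0]) + rng.normal(0.0, 0.05)
        if c_onset + 120.0 > t[-1]:
            break
        c_wf = _inject_saccade(t, x, y, c_onset, c_amp, _unit(c_ang), profile.velocity_scale)
        occupied.append((c_onset, c_onset + c_wf.duration_ms))
        pos += c_amp * np.array([math.cos(c_ang), math.sin(c_ang)])
        cursor = c_onset + c_wf.duration_ms
        gt.injected_saccades.append({"type": "corrective", "onset_ms": c_onset, "amplitude": c_amp})

    gt.n_blinks = _add_blinks(rng, t, valid, profile.blink_rate, occupied)
    x += _band_limited_noise(rng, t.size, profile.noise_sd_deg)
    y += _band_limited_noise(rng, t.size, profile.noise_sd_deg)
    trace = GazeTrace(trial_id=trial.trial_id, t=t, x=x, y=y, valid=valid, rate_hz=rate_hz)
    return trace, gt


def simulate_pursuit_trial(
    profile: CohortProfile,
    trial: TrialRecord,
    rng: np.random.Generator,
    rate_hz: float = 250.0,
) -> tuple[GazeTrace, GroundTruth]:
    """Sinusoidal pursuit: eye velocity = gain x target velocity; the
    accumulating positional lag triggers catch-up saccades once the error
    stays above threshold, at a propensity set by ``catchup_rate``."""
    gain = profile.pursuit_gain_h if trial.pursuit_axis == "horizontal" else profile.pursuit_gain_v
    t = _time_grid(trial.duration_ms, rate_hz)
    dt_s = (t[1] - t[0]) / 1000.0
    a = trial.pursuit_amplitude_deg
    f = trial.pursuit_freq_hz
    t_s = t / 1000.0
    target = a * np.sin(2.0 * math.pi * f * t_s)
    target_v = a * 2.0 * math.pi * f * np.cos(2.0 * math.pi * f * t_s)

    # smooth component: integral of gain * target velocity
    eye = np.concatenate(([0.0], np.cumsum(gain * target_v[:-1] * dt_s)))
    gt = GroundTruth(trial_id=trial.trial_id, true_gain=gain)

    # catch-up saccades: error above threshold sustained >= 60 ms, then a
    # per-sample firing probability proportional to catchup_rate
    p_fire = min(1.0, profile.catchup_rate / 25.0)
    sustain_n = max(1, int(round(60.0 / (dt_s * 1000.0))))
    thresh = profile.catchup_threshold_deg
    along = np.zeros(t.size)  # injected saccadic displacement, cumulative
    sustained = 0
    i = 0
    occupied: list[tuple[float, float]] = []
    while i < t.size:
        err = target[i] - (eye[i] + along[i])
        if abs(err) > thresh:
            sustained += 1
        else:
            sustained = 0
        if sustained >= sustain_n and rng.random() < p_fire:
            amp = abs(err) + 0.8  # lead the target slightly
            direction = 1.0 if err > 0 else -1.0
            wf = SaccadeWaveform(amplitude=amp, velocity_scale=profile.velocity_scale)
            rel = t - t[i]
            disp = np.where(rel <= 0, 0.0,
                            np.where(rel >= wf.duration_ms, amp, wf.displacement(rel)))
            along += direction * disp
            occupied.append((t[i], t[i] + wf.duration_ms))
            gt.injected_saccades.append(
                {"type": "catchup", "onset_ms": float(t[i]), "amplitude": amp}
            )
            gt.n_catchup += 1
            sustained = 0
            i += int(round(wf.duration_ms / (dt_s * 1000.0))) + 1
            continue
        i += 1
    eye = eye + along

    valid = np.ones(t.size, dtype=bool)
    gt.n_blinks = _add_blinks(rng, t, valid, profile.blink_rate, occupied)
    noise_on = _band_limited_noise(rng, t.size, profile.noise_sd_deg)
    noise_off = _band_limited_noise(rng, t.size, profile.noise_sd_deg)
    if trial.pursuit_axis == "horizontal":
        x, y = eye + noise_on, noise_off
    else:
        x, y = noise_off, eye + noise_on
    trace = GazeTrace(trial_id=trial.trial_id, t=t, x=x, y=y, valid=valid, rate_hz=rate_hz)
    return trace, gt


def simulate_trial(
    profile: CohortProfile,
    trial: TrialRecord,
    rng: np.random.Generator,
    rate_hz: float = 250.0,
) -> tuple[GazeTrace, GroundTruth]:
    """Dispatch on the trial's task."""
    if trial.task == "fixation":
        return simulate_fixation_trial(profile, trial, rng, rate_hz)
    if trial.task == "saccade":
        return simulate_saccade_trial(profile, trial, rng, rate_hz)
    if trial.task == "pursuit":
        return simulate_pursuit_trial(profile, trial, rng, rate_hz)
    raise ValueError(f"unknown task {trial.task!r}")
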