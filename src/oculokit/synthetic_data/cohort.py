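"""Cohort assembly: participants, schedules, traces, ground truth and
pseudo neuropsychological scores.

Reproducibility: one integer root seed; per-participant random substreams
are spawned from a ``SeedSequence`` so trials are independent and the
whole cohort is byte-identical for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..io_types import GazeTrace, ScheduleConfig, TrialRecord
from .profiles import CohortProfile
from .schedule import build_task_schedule
from .trials import GroundTruth, simulate_trial

__all__ = ["CohortData", "make_cohort", "pseudo_scores", "SCORE_NAMES"]

# basic visual / visuospatial / visuoperceptual pseudo-tests load on the
# oculomotor phenotype; the non-visual pair does not
SCORE_NAMES: dict[str, bool] = {
    "figure_ground": True,
    "shape_discrimination": True,
    "dot_counting": True,
    "number_location": True,
    "object_decision": True,
    "fragmented_letters": True,
    "arithmetic": False,
    "word_recognition": False,
}


@dataclass
class CohortData:
    participants: pd.DataFrame            # participant_id, group, age, ...
    schedule: list[TrialRecord]
    traces: dict[str, dict[str, GazeTrace]] = field(repr=False, default_factory=dict)
    ground_truth: dict[str, dict[str, GroundTruth]] = field(repr=False, default_factory=dict)
    scores: pd.DataFrame | None = None

    def participant_ids(self) -> list[str]:
        return list(self.participants["participant_id"])


def _individualize(
    profile: CohortProfile, rng: np.random.Generator
) -> CohortProfile:
    """Draw one participant's parameters around the group profile."""
    s = profile.subject_sd_frac
    if s <= 0:
        return profile
    return profile.replace(
        latency_median_ms=float(profile.latency_median_ms * rng.lognormal(0.0, s)),
        saccadic_gain=float(np.clip(profile.saccadic_gain * rng.lognormal(0.0, s / 2), 0.2, 1.5)),
        pursuit_gain_h=float(np.clip(profile.pursuit_gain_h * rng.lognormal(0.0, s / 2), 0.05, 1.5)),
        pursuit_gain_v=float(np.clip(profile.pursuit_gain_v * rng.lognormal(0.0, s / 2), 0.05, 1.5)),
        swj_rate=float(profile.swj_rate * rng.lognormal(0.0, 2 * s)),
        intrusion_rate=float(profile.intrusion_rate * rng.lognormal(0.0, 2 * s)),
        overlap_penalty_ms=float(profile.overlap_penalty_ms * rng.lognormal(0.0, s)),
        velocity_scale=float(np.clip(profile.velocity_scale * rng.lognormal(0.0, s / 2), 0.5, 2.0)),
    )


def pseudo_scores(
    latencies: Sequence[float],
    loadings: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Scores correlated with participant latency at the given loadings.

    Each column j is ``loading_j * z(latency) + sqrt(1 - loading_j^2) * e``
    so its population Pearson correlation with latency is ``loading_j``.
    """
    lat = np.asarray(latencies, dtype=float)
    sd = lat.std()
    z = (lat - lat.mean()) / sd if sd > 0 else np.zeros_like(lat)
    cols = {}
    for name, loading in loadings.items():
        eps = rng.standard_normal(lat.size)
        cols[name] = loading * z + np.sqrt(max(0.0, 1.0 - loading**2)) * eps
    return pd.DataFrame(cols)


def make_cohort(
    profiles: Sequence[CohortProfile] | Mapping[str, CohortProfile],
    schedule_config: ScheduleConfig | None = None,
    seed: int = 0,
    tasks: Sequence[str] = ("fixation", "saccade", "pursuit"),
    include_practice: bool = True,
) -> CohortData:
    """Simulate a full cohort: schedule, traces, ground truth, scores.

    ``tasks`` can be restricted to speed up targeted experiments.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    if not profiles:
        raise ValueError("need at least one cohort profile")
    cfg = schedule_config or ScheduleConfig()
    root = np.random.SeedSequence(seed)
    n_total = sum(p.n_participants for p in profiles)
    streams = root.spawn(n_total + 1)
    schedule = build_task_schedule(cfg, np.random.default_rng(streams[0]))
    trials = [
        tr for tr in schedule
        if tr.task in tasks and (include_practice or not tr.practice)
    ]

    rows = []
    traces: dict[str, dict[str, GazeTrace]] = {}
    truth: dict[str, dict[str, GroundTruth]] = {}
    k = 1
    for profile in profiles:
        for i in range(profile.n_participants):
            rng = np.random.default_rng(streams[k])
            k += 1
            pid = f"{profile.group_label}-{i + 1:02d}"
            age = float(rng.normal(profile.age_mean, profile.age_sd))
            indiv = _individualize(profile, rng)
            traces[pid] = {}
            truth[pid] = {}
            for tr in trials:
                trace, gt = simulate_trial(indiv, tr, rng, rate_hz=cfg.sample_rate_hz)
                traces[pid][tr.trial_id] = trace
                truth[pid][tr.trial_id] = gt
            rows.append({
                "participant_id": pid,
                "group": profile.group_label,
                "age": age,
                "latency_median_ms": indiv.latency_median_ms,
                "saccadic_gain": indiv.saccadic_gain,
                "pursuit_gain_h": indiv.pursuit_gain_h,
                "pursuit_gain_v": indiv.pursuit_gain_v,
                "overlap_penalty_ms": indiv.overlap_penalty_ms,
                "pseudo_score_loading": profile.pseudo_score_loading,
            })
    participants = pd.DataFrame(rows)

    # pseudo neuropsych scores, correlated with true participant latency
    score_rng = np.random.default_rng(root.spawn(1)[0])
    frames = []
    for profile in profiles:
        sub = participants[participants["group"] == profile.group_label]
        loadings = {
            name: (profile.pseudo_score_loading if visual else 0.0)
            for name, visual in SCORE_NAMES.items()
        }
        sc = pseudo_scores(sub["latency_median_ms"].to_numpy(), loadings, score_rng)
        sc.index = pd.Index(sub["participant_id"], name="participant_id")
        frames.append(sc)
    scores = pd.concat(frames)

    return CohortData(
        participants=participants,
        schedule=schedule,
        traces=traces,
        ground_truth=truth,
        scores=scores,
    )
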