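"""Cohort phenotype parameter sets for the simulator.

The default profiles are calibrated only to reproduce the qualitative
group ordering observed clinically (PCA worst on saccade metrics and
markedly hypometric with a large overlap penalty; typical Alzheimer's
disease with frequent square wave jerks and elevated saccadic velocity;
controls at baseline), never any exact cohort value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["CohortProfile", "default_profiles"]


@dataclass
class CohortProfile:
    group_label: str
    n_participants: int = 10
    age_mean: float = 63.0
    age_sd: float = 6.0
    swj_rate: float = 0.6               # square wave jerks / fixation trial
    intrusion_rate: float = 0.3         # large intrusive saccades / trial
    latency_median_ms: float = 200.0    # log-normal median
    latency_sigma: float = 0.18         # log-normal shape
    overlap_penalty_ms: float = 30.0
    saccadic_gain: float = 0.95         # expected amplitude / eccentricity
    velocity_scale: float = 1.0         # main-sequence peak multiplier
    pursuit_gain_h: float = 0.90
    pursuit_gain_v: float = 0.67
    catchup_rate: float = 2.0           # catch-up saccade propensity
    blink_rate: float = 0.5             # blinks / 10 s trial
    noise_sd_deg: float = 0.05  # band-limited; larger values bias the gain trim
    pseudo_score_loading: float = 0.3   # corr(pseudo score, latency)
    # secondary knobs
    wrong_direction_prob: float = 0.02
    amplitude_noise_frac: float = 0.08
    subject_sd_frac: float = 0.10       # between-participant spread of key params
    catchup_threshold_deg: float = 1.5

    def __post_init__(self) -> None:
        for name in ("swj_rate", "intrusion_rate", "catchup_rate", "blink_rate",
                     "overlap_penalty_ms", "noise_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("saccadic_gain", "pursuit_gain_h", "pursuit_gain_v"):
            g = getattr(self, name)
            if not 0.0 < g <= 1.5:
                raise ValueError(f"{name} must be in (0, 1.5], got {g}")
        if self.latency_sigma <= 0:
            raise ValueError("latency_sigma must be > 0")
        if not 0.0 <= self.wrong_direction_prob <= 1.0:
            raise ValueError("wrong_direction_prob must be a probability")
        if not -1.0 <= self.pseudo_score_loading <= 1.0:
            raise ValueError("pseudo_score_loading must be in [-1, 1]")

    def replace(self, **overrides) -> "CohortProfile":
        return dataclasses.replace(self, **overrides)


def default_profiles() -> dict[str, CohortProfile]:
    """Control / typical-AD / PCA phenotypes with the expected ordering."""
    return {
        "control": CohortProfile(
            group_label="control",
            age_mean=63.3, age_sd=6.2,
            swj_rate=0.6, intrusion_rate=0.3,
            latency_median_ms=200.0, latency_sigma=0.18, overlap_penalty_ms=30.0,
            saccadic_gain=0.95, velocity_scale=1.0,
            pursuit_gain_h=0.90, pursuit_gain_v=0.67,
            catchup_rate=2.0, blink_rate=0.5,
            wrong_direction_prob=0.02, pseudo_score_loading=0.3,
        ),
        "tAD": CohortProfile(
            group_label="tAD",
            age_mean=67.4, age_sd=5.9,
            swj_rate=3.0, intrusion_rate=0.8,
            latency_median_ms=215.0, latency_sigma=0.20, overlap_penalty_ms=40.0,
            saccadic_gain=0.93, velocity_scale=1.2,
            pursuit_gain_h=0.78, pursuit_gain_v=0.55,
            catchup_rate=4.0, blink_rate=0.8,
            wrong_direction_prob=0.04, pseudo_score_loading=0.3,
        ),
        "PCA": CohortProfile(
            group_label="PCA",
            age_mean=63.2, age_sd=8.9,
            swj_rate=1.5, intrusion_rate=2.5,
            latency_median_ms=330.0, latency_sigma=0.30, overlap_penalty_ms=110.0,
            saccadic_gain=0.75, velocity_scale=1.0,
            pursuit_gain_h=0.72, pursuit_gain_v=0.50,
            catchup_rate=6.0, blink_rate=1.0,
            wrong_direction_prob=0.12, pseudo_score_loading=0.8,
        ),
    }
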