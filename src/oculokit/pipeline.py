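"""Pipeline glue: traces + schedule -> events -> long metrics table.

Metric names emitted (one row per participant x trial, except the
per-participant ``longest_fixation_ms``):

========================  =======================================
``swj_count``             square wave jerks per fixation trial
``large_intrusive_saccades``  blink-free >2 deg saccades per fixation trial
``longest_fixation_ms``   longest inter-saccade interval, all trials
``time_to_target_ms``     target onset -> first fixation within 2.5 deg
``latency_ms``            target onset -> main saccade onset
``amplitude_error_deg``   main saccade amplitude - eccentricity
``peak_velocity``         main saccade peak velocity (deg/s)
``n_saccades``            blink-free >2 deg saccades after target onset
``pursuit_gain``          mean trimmed instantaneous gain per trial
``pursuit_saccades``      blink-free >2 deg saccades per pursuit trial
========================  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .event_detection import ParserParams, parse_trace
from .fixation_metrics import (
    count_large_intrusive_saccades,
    count_square_wave_jerks,
    longest_fixation_period,
)
from .io_types import Config, GazeTrace, MetricsRow, TrialRecord
from .pursuit_metrics import analyze_pursuit_trial
from .saccade_metrics import (
    MainSaccadeResult,
    count_trial_saccades,
    identify_main_saccade,
    removal_rate,
    time_to_first_target_fixation,
)

__all__ = ["ParsedTrial", "parse_all", "compute_metrics", "removal_rates", "parser_params"]


@dataclass
class ParsedTrial:
    trial: TrialRecord
    saccades: list = field(default_factory=list)
    fixations: list = field(default_factory=list)
    blinks: list = field(default_factory=list)


def parser_params(config: Config) -> ParserParams:
    p = config.parser
    return ParserParams(
        velocity_threshold=p.velocity_threshold,
        acceleration_threshold=p.acceleration_threshold,
        min_saccade_duration_ms=p.min_saccade_duration_ms,
        min_fixation_duration_ms=p.min_fixation_duration_ms,
        blink_pad_ms=p.blink_pad_ms,
        smooth=p.smooth,
    )


def parse_all(
    traces: Mapping[str, GazeTrace],
    schedule: Sequence[TrialRecord],
    params: ParserParams,
) -> dict[str, ParsedTrial]:
    """Parse every trace that has a matching trial record."""
    by_id = {tr.trial_id: tr for tr in schedule}
    out: dict[str, ParsedTrial] = {}
    for trial_id, trace in traces.items():
        if trial_id not in by_id:
            continue
        saccades, fixations, blinks = parse_trace(trace, params)
        out[trial_id] = ParsedTrial(
            trial=by_id[trial_id], saccades=saccades, fixations=fixations, blinks=blinks
        )
    return out


def compute_metrics(
    traces_by_participant: Mapping[str, Mapping[str, GazeTrace]],
    schedule: Sequence[TrialRecord],
    participants: pd.DataFrame,
    config: Config | None = None,
) -> tuple[pd.DataFrame, dict[str, list[MainSaccadeResult]]]:
    """Compute the long metrics table for a whole cohort.

    Returns ``(metrics, main_results)`` where ``metrics`` has one
    :class:`MetricsRow` per row and ``main_results`` holds the per-trial
    main-saccade outcomes per participant (for removal-rate reporting).
    Practice trials are discarded.
    """
    cfg = config or Config()
    params = parser_params(cfg)
    ana = cfg.analysis
    meta = participants.set_index("participant_id")
    rows: list[MetricsRow] = []
    main_results: dict[str, list[MainSaccadeResult]] = {}

    for pid, traces in traces_by_participant.items():
        group = str(meta.loc[pid, "group"])
        age = float(meta.loc[pid, "age"])
        parsed = parse_all(traces, schedule, params)
        fixation_trials = []
        results: list[MainSaccadeResult] = []

        for trial_id in sorted(parsed):
            pt = parsed[trial_id]
            trial = pt.trial
            if trial.practice:
                continue
            common = dict(participant_id=pid, group=group, age=age, trial_id=trial_id)
            if trial.task == "fixation":
                trace = traces[trial_id]
                fixation_trials.append(
                    (pt.saccades, (float(trace.t[0]), float(trace.t[-1])))
                )
                n_swj, _ = count_square_wave_jerks(
                    pt.saccades,
                    target_xy=trial.target_location or (0.0, 0.0),
                    max_amplitude_deg=ana.swj_max_amplitude_deg,
                    max_interval_ms=ana.swj_max_interval_ms,
                    max_amplitude_diff_deg=ana.swj_max_amplitude_diff_deg,
                    interval_anchor=ana.swj_interval_anchor,
                )
                rows.append(MetricsRow(**common, metric_name="swj_count", value=n_swj))
                rows.append(MetricsRow(
                    **common, metric_name="large_intrusive_saccades",
                    value=count_large_intrusive_saccades(
                        pt.saccades, ana.large_saccade_min_amplitude_deg
                    ),
                ))
            elif trial.task == "saccade":
                covar = dict(eccentricity=trial.eccentricity, condition=trial.condition)
                ttf = time_to_first_target_fixation(
                    trial, pt.fixations,
                    radius_deg=ana.target_fixation_radius_deg,
                    response_window_ms=cfg.schedule.response_window_ms,
                )
                rows.append(MetricsRow(
                    **common, metric_name="time_to_target_ms", value=ttf, **covar
                ))
                res = identify_main_saccade(
                    trial, pt.saccades,
                    max_start_dist_deg=ana.main_saccade_max_start_dist_deg,
                    max_direction_error_deg=ana.main_saccade_max_direction_error_deg,
                    max_ordinal=ana.main_saccade_max_ordinal,
                )
                results.append(res)
                selected = res.status == "selected"
                rows.append(MetricsRow(
                    **common, metric_name="latency_ms",
                    value=res.latency_ms if selected else None, **covar,
                ))
                rows.append(MetricsRow(
                    **common, metric_name="amplitude_error_deg",
                    value=res.amplitude_error_deg if selected else None, **covar,
                ))
                rows.append(MetricsRow(
                    **common, metric_name="peak_velocity",
                    value=res.peak_velocity if selected else None, **covar,
                    saccade_amplitude=res.saccade.amplitude if selected else None,
                ))
                rows.append(MetricsRow(
                    **common, metric_name="n_saccades",
                    value=count_trial_saccades(
                        trial, pt.saccades, ana.large_saccade_min_amplitude_deg
                    ),
                    **covar,
                ))
            elif trial.task == "pursuit":
                result = analyze_pursuit_trial(
                    traces[trial_id], trial, pt.saccades, pt.blinks,
                    pad_ms=ana.pursuit_exclusion_pad_ms,
                    min_target_speed=ana.pursuit_min_target_speed,
                    trim_low=ana.gain_trim_low,
                    trim_high=ana.gain_trim_high,
                )
                axis = dict(axis=trial.pursuit_axis)
                rows.append(MetricsRow(
                    **common, metric_name="pursuit_gain", value=result.mean_gain, **axis
                ))
                rows.append(MetricsRow(
                    **common, metric_name="pursuit_saccades", value=result.n_saccades, **axis
                ))

        if fixation_trials:
            rows.append(MetricsRow(
                participant_id=pid, group=group, age=age, trial_id="all",
                metric_name="longest_fixation_ms",
                value=longest_fixation_period(fixation_trials),
            ))
        if results:
            main_results[pid] = results

    metrics = pd.DataFrame([r.to_dict() for r in rows])
    return metrics, main_results


def removal_rates(main_results: Mapping[str, list[MainSaccadeResult]],
                  groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-group proportion of saccade trials removed by the
    main-saccade algorithm."""
    per_group: dict[str, list[MainSaccadeResult]] = {}
    for pid, results in main_results.items():
        per_group.setdefault(groups[pid], []).extend(results)
    return pd.DataFrame([
        {"group": g, "removal_rate": removal_rate(res), "n_trials": len(res)}
        for g, res in sorted(per_group.items())
    ])
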