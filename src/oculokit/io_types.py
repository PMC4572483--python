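"""Core data model, trace/event readers-writers and configuration.

Coordinate convention: screen-centred degrees of visual angle, positive
rightward (x) and upward (y).  Time is milliseconds as floats; trial time
zero is trial start (central fixation onset).  Samples lost to blinks or
pupil occlusion are retained as rows with ``valid=False`` rather than
dropped, so exclusion windows can be computed on the time axis.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigError",
    "GazeTrace",
    "SaccadeEvent",
    "FixationEvent",
    "TrialRecord",
    "MetricsRow",
    "ParserConfig",
    "ScheduleConfig",
    "AnalysisConfig",
    "Config",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_schedule",
    "write_schedule",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed data breaches a structural invariant."""


class ConfigError(ValueError):
    """Configuration contains unknown keys or out-of-range values."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GazeTrace:
    """Uniformly sampled gaze positions for one trial.

    Parameters
    ----------
    trial_id : str
        Identifier linking the trace to a :class:`TrialRecord`.
    t : ndarray
        Sample times in ms, strictly increasing with constant step
        ``1000 / rate_hz`` (up to one rounding unit).
    x, y : ndarray
        Horizontal / vertical gaze position in degrees of visual angle.
    valid : ndarray of bool
        False during blinks or pupil loss; ``x``/``y`` may be NaN there.
    rate_hz : float
        Nominal sampling rate (250 by default).
    """

    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float = 250.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if n < 2:
            raise ValidationError(f"trace {self.trial_id!r}: need >= 2 samples, got {n}")
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValidationError(f"trace {self.trial_id!r}: column lengths differ")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            i = int(np.argmax(steps <= 0))
            raise ValidationError(
                f"trace {self.trial_id!r}: time not strictly increasing at sample {i + 1} "
                f"(t={self.t[i + 1]!r})"
            )
        nominal = 1000.0 / self.rate_hz
        if np.any(np.abs(steps - nominal) > 0.5 + 1e-9):
            i = int(np.argmax(np.abs(steps - nominal) > 0.5 + 1e-9))
            raise ValidationError(
                f"trace {self.trial_id!r}: non-uniform step {steps[i]:g} ms at sample "
                f"{i + 1} (expected {nominal:g} ms)"
            )
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(
                f"trace {self.trial_id!r}: non-finite position at valid sample {i}"
            )

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def span_ms(self) -> float:
        """Time covered by the trace, first to last sample."""
        return float(self.t[-1] - self.t[0])


@dataclass
class SaccadeEvent:
    """A parsed saccade with its kinematic summary."""

    onset_ms: float
    offset_ms: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    amplitude: float
    peak_velocity: float
    contains_blink: bool = False
    ordinal: int = 1

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValidationError(
                f"saccade offset {self.offset_ms} must exceed onset {self.onset_ms}"
            )
        if self.amplitude < 0:
            raise ValidationError("saccade amplitude must be >= 0")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    @property
    def displacement(self) -> tuple[float, float]:
        return (
            self.end_xy[0] - self.start_xy[0],
            self.end_xy[1] - self.start_xy[1],
        )


@dataclass
class FixationEvent:
    """A period with no saccadic movement."""

    onset_ms: float
    offset_ms: float
    mean_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValidationError(
                f"fixation offset {self.offset_ms} must exceed onset {self.onset_ms}"
            )

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class TrialRecord:
    """Stimulus timeline and condition for one trial.

    ``task`` is one of ``fixation``, ``saccade``, ``pursuit``.  Saccade
    trials carry a gap/overlap ``condition``, a signed ``target_location``
    and its ``eccentricity``; pursuit trials carry axis, frequency and
    half-range amplitude of the sinusoidal target.
    """

    trial_id: str
    task: str
    condition: str = "none"  # gap | overlap | none
    target_location: tuple[float, float] | None = None
    eccentricity: float | None = None
    fixation_offset_ms: float | None = None
    target_onset_ms: float | None = None
    pursuit_axis: str | None = None  # horizontal | vertical
    pursuit_freq_hz: float | None = None
    pursuit_amplitude_deg: float | None = None
    duration_ms: float = 10_000.0
    practice: bool = False

    def __post_init__(self) -> None:
        if self.task not in ("fixation", "saccade", "pursuit"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.condition not in ("gap", "overlap", "none"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.condition == "gap":
            if self.target_onset_ms - self.fixation_offset_ms != 200.0:
                raise ValidationError(
                    f"trial {self.trial_id!r}: gap requires target onset 200 ms "
                    "after fixation offset"
                )
        elif self.condition == "overlap":
            if self.fixation_offset_ms - self.target_onset_ms != 200.0:
                raise ValidationError(
                    f"trial {self.trial_id!r}: overlap requires target onset 200 ms "
                    "before fixation offset"
                )
        if self.task == "saccade":
            tx, ty = self.target_location
            ecc = math.hypot(tx, ty)
            if abs(ecc - self.eccentricity) > 1e-6:
                raise ValidationError(
                    f"trial {self.trial_id!r}: eccentricity {self.eccentricity} "
                    f"inconsistent with target location {self.target_location}"
                )


@dataclass
class MetricsRow:
    """One participant x trial x metric observation (long format)."""

    participant_id: str
    group: str
    age: float
    trial_id: str
    metric_name: str
    value: float | None
    eccentricity: float | None = None
    condition: str | None = None
    axis: str | None = None
    saccade_amplitude: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ("t_ms", "x_deg", "y_deg", "valid")


def read_trace(path: str | Path, dialect: str = "csv", trial_id: str | None = None,
               rate_hz: float = 250.0) -> GazeTrace:
    """Read a gaze trace from ``path``.

    ``dialect='csv'`` expects columns ``t_ms, x_deg, y_deg, valid``;
    ``dialect='asc'`` accepts an EyeLink-style whitespace sample listing
    (``<t> <x> <y> ...`` with ``.`` marking missing samples; non-numeric
    lines are skipped).  Unparseable rows are reported with line numbers.
    """
    path = Path(path)
    if dialect not in ("csv", "asc"):
        raise ValueError(f"unknown trace dialect {dialect!r}")
    if trial_id is None:
        trial_id = path.stem
    if dialect == "csv":
        t, x, y, valid = _read_trace_csv(path)
    else:
        t, x, y, valid = _read_trace_asc(path)
    return GazeTrace(trial_id=trial_id, t=t, x=x, y=y, valid=valid, rate_hz=rate_hz)


def _read_trace_csv(path: Path):
    t, x, y, valid = [], [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _TRACE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            ok = row["valid"].strip().lower() in ("1", "true", "t", "yes")
            try:
                t.append(float(row["t_ms"]))
                if ok:
                    x.append(float(row["x_deg"]))
                    y.append(float(row["y_deg"]))
                else:
                    x.append(_float_or_nan(row["x_deg"]))
                    y.append(_float_or_nan(row["y_deg"]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row ({exc})") from None
            valid.append(ok)
    return np.array(t), np.array(x), np.array(y), np.array(valid, dtype=bool)


def _float_or_nan(s: str) -> float:
    s = s.strip()
    if s in ("", ".", "nan", "NaN"):
        return math.nan
    return float(s)


def _read_trace_asc(path: Path):
    t, x, y, valid = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 3 or not parts[0].replace(".", "", 1).isdigit():
                continue  # MSG / event / header line
            try:
                ti = float(parts[0])
            except ValueError:
                continue
            if parts[1] == "." or parts[2] == ".":
                t.append(ti)
                x.append(math.nan)
                y.append(math.nan)
                valid.append(False)
            else:
                try:
                    t.append(ti)
                    x.append(float(parts[1]))
                    y.append(float(parts[2]))
                    valid.append(True)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: unparseable sample ({exc})") from None
    return np.array(t), np.array(x), np.array(y), np.array(valid, dtype=bool)


def write_trace(trace: GazeTrace, path: str | Path) -> None:
    """Write a trace as CSV (columns ``t_ms, x_deg, y_deg, valid``)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRACE_COLUMNS)
        for ti, xi, yi, vi in zip(trace.t, trace.x, trace.y, trace.valid):
            writer.writerow([
                repr(float(ti)),
                "" if math.isnan(xi) else repr(float(xi)),
                "" if math.isnan(yi) else repr(float(yi)),
                int(vi),
            ])


# ---------------------------------------------------------------------------
# Event I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = (
    "event_type", "trial_id", "ordinal", "onset_ms", "offset_ms",
    "start_x", "start_y", "end_x", "end_y", "amplitude", "peak_velocity",
    "contains_blink", "mean_x", "mean_y",
)


def write_events(events: Iterable[SaccadeEvent | FixationEvent], path: str | Path,
                 trial_id: str = "") -> None:
    """Write parsed events (saccades and/or fixations) to a CSV table.

    One row per event, stable column order.  Overlapping saccade
    intervals raise :class:`ValidationError`.
    """
    events = list(events)
    saccades = sorted(
        (e for e in events if isinstance(e, SaccadeEvent)), key=lambda s: s.onset_ms
    )
    for a, b in zip(saccades, saccades[1:]):
        if b.onset_ms < a.offset_ms:
            raise ValidationError(
                f"overlapping saccades at {a.onset_ms}-{a.offset_ms} and "
                f"{b.onset_ms}-{b.offset_ms} ms"
            )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EVENT_COLUMNS)
        for e in events:
            if isinstance(e, SaccadeEvent):
                writer.writerow([
                    "saccade", trial_id, e.ordinal, repr(e.onset_ms), repr(e.offset_ms),
                    repr(e.start_xy[0]), repr(e.start_xy[1]),
                    repr(e.end_xy[0]), repr(e.end_xy[1]),
                    repr(e.amplitude), repr(e.peak_velocity),
                    int(e.contains_blink), "", "",
                ])
            elif isinstance(e, FixationEvent):
                writer.writerow([
                    "fixation", trial_id, "", repr(e.onset_ms), repr(e.offset_ms),
                    "", "", "", "", "", "", "",
                    repr(e.mean_xy[0]), repr(e.mean_xy[1]),
                ])
            else:
                raise TypeError(f"unsupported event type {type(e).__name__}")


def read_events(path: str | Path) -> tuple[list[SaccadeEvent], list[FixationEvent]]:
    """Read an event table written by :func:`write_events`."""
    saccades: list[SaccadeEvent] = []
    fixations: list[FixationEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _EVENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for row in reader:
            if row["event_type"] == "saccade":
                saccades.append(SaccadeEvent(
                    onset_ms=float(row["onset_ms"]),
                    offset_ms=float(row["offset_ms"]),
                    start_xy=(float(row["start_x"]), float(row["start_y"])),
                    end_xy=(float(row["end_x"]), float(row["end_y"])),
                    amplitude=float(row["amplitude"]),
                    peak_velocity=float(row["peak_velocity"]),
                    contains_blink=bool(int(row["contains_blink"])),
                    ordinal=int(row["ordinal"]),
                ))
            elif row["event_type"] == "fixation":
                fixations.append(FixationEvent(
                    onset_ms=float(row["onset_ms"]),
                    offset_ms=float(row["offset_ms"]),
                    mean_xy=(float(row["mean_x"]), float(row["mean_y"])),
                ))
    return saccades, fixations


# ---------------------------------------------------------------------------
# Schedule I/O
# ---------------------------------------------------------------------------

_SCHEDULE_COLUMNS = (
    "trial_id", "task", "condition", "target_x", "target_y", "eccentricity",
    "fixation_offset_ms", "target_onset_ms", "pursuit_axis", "pursuit_freq_hz",
    "pursuit_amplitude_deg", "duration_ms", "practice",
)


def write_schedule(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a trial schedule as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCHEDULE_COLUMNS)
        for tr in trials:
            tx, ty = tr.target_location if tr.target_location else ("", "")
            writer.writerow([
                tr.trial_id, tr.task, tr.condition, tx, ty,
                "" if tr.eccentricity is None else tr.eccentricity,
                "" if tr.fixation_offset_ms is None else tr.fixation_offset_ms,
                "" if tr.target_onset_ms is None else tr.target_onset_ms,
                tr.pursuit_axis or "",
                "" if tr.pursuit_freq_hz is None else tr.pursuit_freq_hz,
                "" if tr.pursuit_amplitude_deg is None else tr.pursuit_amplitude_deg,
                tr.duration_ms, int(tr.practice),
            ])


def read_schedule(path: str | Path) -> list[TrialRecord]:
    """Read a trial schedule written by :func:`write_schedule`."""
    def opt(v: str) -> float | None:
        return None if v == "" else float(v)

    trials: list[TrialRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _SCHEDULE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for row in reader:
            loc = None
            if row["target_x"] != "" and row["target_y"] != "":
                loc = (float(row["target_x"]), float(row["target_y"]))
            trials.append(TrialRecord(
                trial_id=row["trial_id"], task=row["task"], condition=row["condition"],
                target_location=loc, eccentricity=opt(row["eccentricity"]),
                fixation_offset_ms=opt(row["fixation_offset_ms"]),
                target_onset_ms=opt(row["target_onset_ms"]),
                pursuit_axis=row["pursuit_axis"] or None,
                pursuit_freq_hz=opt(row["pursuit_freq_hz"]),
                pursuit_amplitude_deg=opt(row["pursuit_amplitude_deg"]),
                duration_ms=float(row["duration_ms"]),
                practice=bool(int(row["practice"])),
            ))
    return trials


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ParserConfig:
    velocity_threshold: float = 30.0       # deg/s
    acceleration_threshold: float = 8000.0  # deg/s^2
    min_saccade_duration_ms: float = 8.0
    min_fixation_duration_ms: float = 40.0
    blink_pad_ms: float = 50.0
    smooth: bool = False  # optional 3-sample moving average before differencing

    def validate(self) -> None:
        for name in ("velocity_threshold", "acceleration_threshold",
                     "min_saccade_duration_ms", "min_fixation_duration_ms",
                     "blink_pad_ms"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"parser.{name} must be strictly positive, got {v!r}")


@dataclass
class ScheduleConfig:
    sample_rate_hz: float = 250.0
    # fixation task
    fixation_practice_trials: int = 1
    fixation_scored_trials: int = 3
    fixation_duration_ms: float = 10_000.0
    # saccade task
    saccade_blocks: int = 4
    central_fixation_duration_ms: float = 500.0
    gap_ms: float = 200.0
    overlap_ms: float = 200.0
    horizontal_eccentricities: tuple = (5.0, 10.0, 15.0)
    vertical_eccentricities: tuple = (5.0, 10.0)
    response_window_ms: float = 5_000.0
    # pursuit task
    pursuit_practice_trials: int = 2
    pursuit_scored_per_axis: int = 3
    pursuit_freq_hz: float = 0.25
    pursuit_amplitude_deg: float = 10.0
    pursuit_duration_ms: float = 10_000.0

    def validate(self) -> None:
        positive = (
            "sample_rate_hz", "fixation_duration_ms", "central_fixation_duration_ms",
            "gap_ms", "overlap_ms", "response_window_ms", "pursuit_freq_hz",
            "pursuit_amplitude_deg", "pursuit_duration_ms",
        )
        for name in positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"schedule.{name} must be strictly positive, got {v!r}")
        for name in ("fixation_scored_trials", "saccade_blocks", "pursuit_scored_per_axis"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"schedule.{name} must be a positive integer, got {v!r}")

    @property
    def target_locations(self) -> list[tuple[float, float]]:
        """Signed target locations: +-ecc on each axis."""
        locs: list[tuple[float, float]] = []
        for e in self.horizontal_eccentricities:
            locs += [(float(e), 0.0), (-float(e), 0.0)]
        for e in self.vertical_eccentricities:
            locs += [(0.0, float(e)), (0.0, -float(e))]
        return locs


@dataclass
class AnalysisConfig:
    swj_max_amplitude_deg: float = 2.0
    swj_max_interval_ms: float = 300.0
    swj_max_amplitude_diff_deg: float = 0.75
    swj_interval_anchor: str = "offset_to_onset"  # or "onset_to_onset"
    target_fixation_radius_deg: float = 2.5
    main_saccade_max_start_dist_deg: float = 2.5
    main_saccade_max_direction_error_deg: float = 45.0
    main_saccade_max_ordinal: int = 5
    large_saccade_min_amplitude_deg: float = 2.0
    pursuit_exclusion_pad_ms: float = 50.0
    pursuit_min_target_speed: float = 2.0   # deg/s; 0 = keep every sample
    gain_trim_low: float = -1.0
    gain_trim_high: float = 2.0
    trim_z: float = 2.0

    def validate(self) -> None:
        if self.swj_interval_anchor not in ("offset_to_onset", "onset_to_onset"):
            raise ConfigError(
                f"analysis.swj_interval_anchor must be 'offset_to_onset' or "
                f"'onset_to_onset', got {self.swj_interval_anchor!r}"
            )
        for name in ("swj_max_amplitude_deg", "swj_max_interval_ms",
                     "swj_max_amplitude_diff_deg", "target_fixation_radius_deg",
                     "large_saccade_min_amplitude_deg", "trim_z"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"analysis.{name} must be strictly positive, got {v!r}")
        if self.pursuit_min_target_speed < 0:
            raise ConfigError("analysis.pursuit_min_target_speed must be >= 0")
        if self.gain_trim_low >= self.gain_trim_high:
            raise ConfigError("analysis.gain_trim_low must be below gain_trim_high")


@dataclass
class Config:
    parser: ParserConfig = field(default_factory=ParserConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    profiles: dict = field(default_factory=dict)  # group label -> profile overrides

    def validate(self) -> None:
        self.parser.validate()
        self.schedule.validate()
        self.analysis.validate()


def _merge_section(cls, data: dict, section: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {unknown}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config, filling defaults for anything unspecified.

    An absent or empty file yields pure defaults.  Unknown keys are
    rejected; out-of-range values raise :class:`ConfigError`.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = raw
    unknown = sorted(set(data) - {"parser", "schedule", "analysis", "profiles"})
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {unknown}")
    cfg = Config(
        parser=_merge_section(ParserConfig, data.get("parser", {}) or {}, "parser"),
        schedule=_merge_section(ScheduleConfig, data.get("schedule", {}) or {}, "schedule"),
        analysis=_merge_section(AnalysisConfig, data.get("analysis", {}) or {}, "analysis"),
        profiles=data.get("profiles", {}) or {},
    )
    cfg.validate()
    return cfg
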