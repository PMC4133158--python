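"""Core data types for free-foraging choice logs.

A recording is a sequence of timestamped lever-press choices made by one
animal living continuously in an operant chamber under a 12 h/12 h
light/dark schedule.  Everything downstream — inter-choice-interval
statistics, burst segmentation, run analysis, choice-model fitting —
operates on the :class:`EventLog` defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CycleSchedule",
    "EventLog",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "assign_cycle_labels",
    "run_full_analysis",
]

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0


class EventLogError(ValueError):
    """Raised for malformed or inconsistent choice logs."""


@dataclass(frozen=True)
class CycleSchedule:
    """Light/dark schedule of the recording environment.

    Parameters
    ----------
    light_onset : float
        Clock hour at which the light cycle begins (e.g. 8.0 for 08:00).
    light_hours : float
        Hours of light per period; the remainder of the period is dark.
    period : float
        Period of the cycle in hours.  Fixed at one day for circadian
        schedules.
    session_start_hour : float
        Clock hour corresponding to timestamp 0 of the log.
    """

    light_onset: float = 8.0
    light_hours: float = 12.0
    period: float = 24.0
    session_start_hour: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.light_hours < self.period):
            raise ValueError(
                f"light_hours must lie in (0, {self.period}); got {self.light_hours}"
            )

    def clock_hour(self, t_seconds: np.ndarray | float) -> np.ndarray | float:
        """Clock hour of day for a timestamp in seconds from session start."""
        hours = np.asarray(t_seconds, dtype=float) / SECONDS_PER_HOUR
        return (self.session_start_hour + hours) % self.period

    def is_light(self, t_seconds: np.ndarray | float) -> np.ndarray:
        """Whether each timestamp falls in the light cycle.

        Cycle intervals are half-open: ``[light_onset, light_onset + light_hours)``
        is light, so an event exactly at light onset is labelled light.
        """
        h = np.asarray(self.clock_hour(t_seconds), dtype=float)
        rel = (h - self.light_onset) % self.period
        return rel < self.light_hours


@dataclass
class EventLog:
    """A timestamped, option-labelled sequence of choices.

    ``timestamps`` are seconds from session start and strictly increasing;
    ``options`` holds one opaque option identifier (int) per event.
    """

    timestamps: np.ndarray
    options: np.ndarray
    schedule: CycleSchedule = field(default_factory=CycleSchedule)
    duration: float | None = None
    labels: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.options = np.asarray(self.options, dtype=np.int64)
        if self.timestamps.ndim != 1:
            raise EventLogError("timestamps must be one-dimensional")
        if self.timestamps.size == 0:
            raise EventLogError("empty log: no events")
        if self.timestamps.size != self.options.size:
            raise EventLogError(
                f"{self.timestamps.size} timestamps but {self.options.size} options"
            )
        if self.timestamps[0] < 0:
            raise EventLogError("timestamps must be non-negative")
        if np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise EventLogError(
                f"timestamps must be strictly increasing (violated at event {bad})"
            )
        if self.duration is None:
            self.duration = float(self.timestamps[-1])
        elif self.duration < self.timestamps[-1]:
            raise EventLogError("duration is shorter than the last timestamp")
        if self.labels is not None:
            missing = set(np.unique(self.options)) - set(self.labels)
            if missing:
                raise EventLogError(f"options {sorted(missing)} missing from labels")

    @property
    def n_events(self) -> int:
        return int(self.timestamps.size)

    @property
    def option_set(self) -> np.ndarray:
        return np.unique(self.options)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.timestamps, "option": self.options})
        if self.labels is not None:
            df["flavor"] = df["option"].map(dict(self.labels))
        return df


def assign_cycle_labels(log: EventLog) -> np.ndarray:
    """Label every event ``"light"`` or ``"dark"`` by its clock time.

    The light interval is half-open, ``[onset, onset + light_hours)``, so the
    labels partition the events.
    """
    light = log.schedule.is_light(log.timestamps)
    return np.where(light, "light", "dark")


def _parse_option_column(raw: pd.Series) -> tuple[np.ndarray, dict[int, str] | None]:
    """Map an option column to integer codes, preserving labels if textual."""
    if pd.api.types.is_integer_dtype(raw):
        return raw.to_numpy(dtype=np.int64), None
    codes, uniques = pd.factorize(raw.astype(str), sort=True)
    return codes.astype(np.int64), dict(enumerate(uniques))


def read_event_log(
    path: str | Path, schedule: CycleSchedule | None = None
) -> EventLog:
    """Read a choice log from CSV with columns ``time_s,option``.

    Option identifiers may be integers or strings; strings are factorized
    into integer codes (sorted) and retained as labels.  Extra columns
    (``day``, ``flavor``, ``location``) are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EventLogError(f"{path}: empty file") from None
    for col in ("time_s", "option"):
        if col not in df.columns:
            raise EventLogError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        raise EventLogError(f"{path}: no event rows")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax()) + 2  # +1 header, +1 one-based
        raise EventLogError(f"{path}: unparseable time_s at line {row}")
    options, labels = _parse_option_column(df["option"])
    return EventLog(
        timestamps=times.to_numpy(dtype=float),
        options=options,
        schedule=schedule or CycleSchedule(),
        labels=labels,
    )


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write a log back to canonical ``time_s,option`` CSV.

    Round-trips bit-exactly with :func:`read_event_log` for integer options
    and ``repr``-precision floats.
    """
    df = pd.DataFrame({"time_s": log.timestamps, "option": log.options})
    if log.labels is not None:
        df["option"] = df["option"].map(dict(log.labels))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline entry point
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG_KEYS = ("options",)


def run_full_analysis(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Run the complete descriptive + model pipeline on one log.

    ``config`` must name either an input CSV (``log``) or a synthetic
    generation block (``synthetic``), plus the option set.  Deterministic
    given config and seed.  Returns (and optionally writes) a result bundle
    with temporal statistics, the bimodal interval fit, run/rank statistics,
    and choice-model comparison.
    """
    from . import dual_control, run_analysis, synthetic_data, tail_fitting, temporal_stats

    for key in _REQUIRED_CONFIG_KEYS:
        if key not in config:
            raise KeyError(f"configuration missing required key '{key}'")
    if "log" not in config and "synthetic" not in config:
        raise KeyError("configuration must contain either 'log' or 'synthetic'")

    seed = int(config.get("seed", 0))
    if "log" in config:
        schedule = CycleSchedule(**config.get("schedule", {}))
        log = read_event_log(config["log"], schedule=schedule)
    else:
        log = synthetic_data.generate_dataset(
            synthetic_data.SyntheticConfig.from_dict(
                {**config["synthetic"], "seed": seed}
            )
        )

    icis = temporal_stats.interchoice_intervals(log)
    bundle: dict = {
        "n_events": log.n_events,
        "duration_s": log.duration,
        "burstiness": temporal_stats.burstiness(icis),
        "memory": temporal_stats.memory_coefficient(icis),
    }

    ac = temporal_stats.autocorrelogram_period(log, bin_hours=1.0)
    bundle["period_hours"] = ac.period

    trace = temporal_stats.choice_entropy_trace(log.options, window=int(config.get("entropy_window", 100)))
    bundle["entropy_mean_bits"] = float(np.mean(trace.entropies)) if trace.entropies.size else None

    try:
        fit = tail_fitting.fit_bimodal(icis)
        bundle["bimodal_fit"] = fit.to_dict()
    except tail_fitting.TailFitError as exc:
        bundle["bimodal_fit"] = {"error": str(exc)}

    ranks = run_analysis.assign_ranks(log.options)
    runs = run_analysis.extract_runs(log.options)
    dist = run_analysis.run_distribution(runs)
    bundle["ranks"] = {str(k): int(v) for k, v in ranks.rank_of.items()}
    bundle["rank_fit"] = ranks.loglinear._asdict() if ranks.loglinear else None
    bundle["max_run_length"] = int(dist.lengths.max())

    variants = config.get("variants", ["dual", "habit"])
    fits = [
        dual_control.fit_choice_model(
            log.options,
            variant=v,
            restarts=int(config.get("restarts", 5)),
            seed=seed + i,
        )
        for i, v in enumerate(variants)
    ]
    bundle["model_comparison"] = dual_control.compare_models(fits).to_dict(orient="records")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=_json_default)
        pd.DataFrame(
            {"interval_s": icis.intervals, "cycle": icis.cycle_labels}
        ).to_csv(out_dir / "icis.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"lag_hours": ac.lags, "autocorrelation": ac.values}
        ).to_csv(out_dir / "autocorrelogram.tsv", sep="\t", index=False)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
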