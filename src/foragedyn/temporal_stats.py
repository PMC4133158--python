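"""Descriptive temporal statistics of choice logs.

Implements the inter-choice-interval (ICI) substrate and the scale-free
burstiness index B = (σ−m)/(σ+m) and memory coefficient M (lag-1
correlation of consecutive intervals) of Goh & Barabási, plus windowed
choice entropy and autocorrelogram-based circadian period estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .event_model import EventLog, assign_cycle_labels

__all__ = [
    "ICISeries",
    "BurstinessSummary",
    "EntropyTrace",
    "Autocorrelogram",
    "TemporalStatsError",
    "interchoice_intervals",
    "burstiness",
    "burstiness_summary",
    "memory_coefficient",
    "choice_entropy_trace",
    "entropy_shuffle_comparison",
    "autocorrelogram_period",
]


class TemporalStatsError(ValueError):
    """Raised when a temporal statistic is undefined for the input."""


@dataclass
class ICISeries:
    """Ordered inter-choice intervals with per-interval light/dark labels.

    ``cycle_labels[i]`` is the cycle of the interval's *starting* event.
    """

    intervals: np.ndarray
    cycle_labels: np.ndarray
    source_indices: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals <= 0):
            raise TemporalStatsError("all inter-choice intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.intervals.size)

    def select(self, cycle: str) -> np.ndarray:
        """Intervals whose starting event lies in ``cycle`` ('light'|'dark')."""
        if cycle == "overall":
            return self.intervals
        return self.intervals[self.cycle_labels == cycle]


@dataclass(frozen=True)
class BurstinessSummary:
    B: float
    M: float
    mean: float
    std: float
    n: int


@dataclass(frozen=True)
class EntropyTrace:
    window: int
    entropies: np.ndarray
    boundaries: np.ndarray  # start trial index of each window


@dataclass(frozen=True)
class Autocorrelogram:
    bin_hours: float
    lags: np.ndarray  # hours
    values: np.ndarray  # normalized, 1 at lag 0
    peak_lags: np.ndarray  # hours
    period: float | None  # hours; None when < 2 qualifying peaks


def interchoice_intervals(log: EventLog) -> ICISeries:
    """Consecutive differences of event timestamps, cycle-labelled.

    Each interval inherits the light/dark label of its starting event.
    """
    if log.n_events < 2:
        raise TemporalStatsError("need at least 2 events to form intervals")
    labels = assign_cycle_labels(log)
    return ICISeries(
        intervals=np.diff(log.timestamps),
        cycle_labels=labels[:-1],
        source_indices=np.arange(log.n_events - 1),
    )


def _as_intervals(icis: ICISeries | np.ndarray) -> np.ndarray:
    if isinstance(icis, ICISeries):
        return icis.intervals
    return np.asarray(icis, dtype=float)


def burstiness(icis: ICISeries | np.ndarray) -> float:
    """Burstiness index B = (σ − m)/(σ + m).

    σ is the population standard deviation of the intervals and m their
    mean.  B = 1 for maximally bursty trains, 0 for a Poisson process, −1
    for a perfectly periodic train.
    """
    x = _as_intervals(icis)
    if x.size < 2:
        raise TemporalStatsError("burstiness needs at least 2 intervals")
    m = float(np.mean(x))
    s = float(np.std(x))  # population σ
    return (s - m) / (s + m)


def memory_coefficient(icis: ICISeries | np.ndarray) -> float:
    """Memory coefficient M: lag-1 correlation of consecutive intervals.

    M = (1/(n−1)) Σ_i (τ_i − m1)(τ_{i+1} − m2)/(σ1 σ2) with m1, σ1 over the
    first n−1 intervals and m2, σ2 over the last n−1 (population σ).
    Positive M means long intervals tend to follow long ones.
    """
    x = _as_intervals(icis)
    n = x.size
    if n < 3:
        raise TemporalStatsError("memory coefficient needs at least 3 intervals")
    a, b = x[:-1], x[1:]
    s1, s2 = float(np.std(a)), float(np.std(b))
    if s1 == 0.0 or s2 == 0.0:
        raise TemporalStatsError(
            "memory coefficient undefined: zero variance in a margin"
        )
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (s1 * s2))


def burstiness_summary(icis: ICISeries | np.ndarray) -> BurstinessSummary:
    x = _as_intervals(icis)
    return BurstinessSummary(
        B=burstiness(x),
        M=memory_coefficient(x),
        mean=float(np.mean(x)),
        std=float(np.std(x)),
        n=int(x.size),
    )


def _window_entropy(window_options: np.ndarray) -> float:
    _, counts = np.unique(window_options, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def choice_entropy_trace(options: np.ndarray, window: int = 100) -> EntropyTrace:
    """Shannon entropy (bits) of choices in consecutive non-overlapping windows.

    Zero entropy marks purely exploitative (deterministic) windows; log2 of
    the option count marks uniform exploration.  A trailing partial window
    is dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    options = np.asarray(options)
    n_windows = options.size // window
    starts = np.arange(n_windows) * window
    ents = np.array(
        [_window_entropy(options[s : s + window]) for s in starts], dtype=float
    )
    return EntropyTrace(window=window, entropies=ents, boundaries=starts)


def entropy_shuffle_comparison(
    options: np.ndarray,
    window: int = 100,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> dict:
    """Windowed entropy of the data vs frequency-preserving random shuffles.

    Shuffling destroys sequential dependence while keeping overall choice
    frequencies; persistent (run-heavy) sequences concentrate options within
    windows and therefore show lower within-window entropy than their
    shuffles.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    options = np.asarray(options)
    rng = np.random.default_rng(seed)
    empirical = choice_entropy_trace(options, window)
    shuffled = np.empty((n_shuffles, empirical.entropies.size))
    for k in range(n_shuffles):
        perm = rng.permutation(options)
        shuffled[k] = choice_entropy_trace(perm, window).entropies
    shuffled_mean = shuffled.mean(axis=0)
    diff = empirical.entropies - shuffled_mean
    return {
        "empirical": empirical.entropies,
        "shuffled_mean": shuffled_mean,
        "difference": diff,
        "mean_difference": float(diff.mean()) if diff.size else float("nan"),
        "fraction_below": float(np.mean(diff < 0)) if diff.size else float("nan"),
    }


def autocorrelogram_period(
    log: EventLog,
    bin_hours: float = 1.0,
    min_peak_separation_hours: float = 12.0,
    min_peak_height: float | None = None,
) -> Autocorrelogram:
    """Periodicity of activity from the autocorrelation of binned event counts.

    Events are binned into counts per ``bin_hours``; the autocorrelation of
    the mean-subtracted counts is normalized to 1 at lag 0.  Peaks are local
    maxima at positive lags above ``min_peak_height`` (default 2/√n_bins,
    roughly twice the noise floor of an uncorrelated count series) separated
    by at least ``min_peak_separation_hours``; the period is the mean
    spacing between successive peaks (the "pitch" of the correlogram).
    With fewer than two qualifying peaks the period is ``None``.
    """
    bin_s = bin_hours * 3600.0
    n_bins = int(np.ceil((log.duration + 1e-9) / bin_s))
    if n_bins < 2:
        raise TemporalStatsError("record too short for an autocorrelogram")
    counts, _ = np.histogram(log.timestamps, bins=n_bins, range=(0.0, n_bins * bin_s))
    x = counts - counts.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise TemporalStatsError("constant event counts: autocorrelation undefined")
    full = signal.correlate(x, x, mode="full")
    ac = full[x.size - 1 :] / denom  # lags 0 .. n_bins-1, ac[0] == 1
    lags = np.arange(ac.size) * bin_hours

    if min_peak_height is None:
        min_peak_height = 2.0 / np.sqrt(n_bins)
    min_dist = max(1, int(round(min_peak_separation_hours / bin_hours)))
    # the biased autocorrelation estimate decays linearly with lag, so peaks
    # are only trusted over the first half of the record
    half = max(2, x.size // 2)
    peaks, _ = signal.find_peaks(ac[1:half], height=min_peak_height, distance=min_dist)
    peak_lags = lags[peaks + 1]
    period = float(np.mean(np.diff(peak_lags))) if peak_lags.size >= 2 else None
    return Autocorrelogram(
        bin_hours=bin_hours,
        lags=lags,
        values=ac,
        peak_lags=peak_lags,
        period=period,
    )
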