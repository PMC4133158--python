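"""Sequential structure of choices: runs, hazard of run ending, ranks.

A *run* is a maximal block of consecutive identical choices.  Persistent
(preferential-attachment) choice produces heavy-tailed run-length
distributions and a hazard of run ending that falls with run length; an
exchangeable sequence produces geometric runs with constant hazard.
Departures from exchangeability are tested by Monte-Carlo comparison
against frequency-preserving shuffles.  Options are ranked by total
consumption and the rank-wise choice percentages summarized by an
ordinary-least-squares fit of percentage on log10(rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "RunSequence",
    "RunDistribution",
    "ShuffleTestResult",
    "RankAssignment",
    "LogLinearFit",
    "RunAnalysisError",
    "extract_runs",
    "run_distribution",
    "shuffle_run_test",
    "assign_ranks",
    "fit_rank_loglinear",
]


class RunAnalysisError(ValueError):
    """Raised for empty or degenerate sequential inputs."""


@dataclass(frozen=True)
class RunSequence:
    """Ordered (option, length) runs of a choice sequence."""

    options: np.ndarray  # option id per run
    lengths: np.ndarray  # run length per run, ≥ 1
    n_trials: int


@dataclass(frozen=True)
class RunDistribution:
    """Survival S(ℓ) = P(L ≥ ℓ) and hazard h(ℓ) of run lengths.

    h(ℓ) = [S(ℓ) − S(ℓ+1)]/S(ℓ), the probability a run ends at exactly
    length ℓ given it reached ℓ; reported only where S(ℓ) > 0.
    """

    lengths: np.ndarray  # 1 .. max length
    survival: np.ndarray
    hazard: np.ndarray
    scope: str = "overall"
    n_runs: int = 0


class LogLinearFit(NamedTuple):
    slope: float
    intercept: float
    adj_r2: float


@dataclass(frozen=True)
class RankAssignment:
    """Options ordered by total consumption; rank 1 = most consumed."""

    rank_of: dict  # option id -> rank (1-based)
    counts: dict  # option id -> total count
    percentages: np.ndarray  # choice percentage by rank (index 0 = rank 1)
    loglinear: LogLinearFit | None


@dataclass(frozen=True)
class ShuffleTestResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_shuffles: int
    seed: int | None
    scope: str


def extract_runs(options: np.ndarray) -> RunSequence:
    """Maximal constant segments of the choice sequence, in order."""
    options = np.asarray(options)
    if options.size == 0:
        raise RunAnalysisError("empty choice sequence")
    change = np.flatnonzero(options[1:] != options[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [options.size - 1]))
    return RunSequence(
        options=options[starts],
        lengths=(ends - starts + 1).astype(np.int64),
        n_trials=int(options.size),
    )


def _run_lengths_survival(lengths: np.ndarray, max_len: int | None = None) -> np.ndarray:
    """S(ℓ) for ℓ = 1..max_len from a vector of run lengths."""
    m = int(max_len or lengths.max())
    counts = np.bincount(lengths, minlength=m + 1)[1 : m + 1]
    ge = counts[::-1].cumsum()[::-1]
    return ge / lengths.size


def run_distribution(
    runs: RunSequence,
    scope: str = "overall",
    ranks: RankAssignment | None = None,
) -> RunDistribution:
    """Survival and hazard of run lengths, overall or for one rank's option.

    ``scope`` is ``"overall"`` or ``"rank:<r>"`` (requires ``ranks``), in
    which case only runs of the option holding rank r are used.
    """
    lengths = runs.lengths
    if scope != "overall":
        if not scope.startswith("rank:") or ranks is None:
            raise RunAnalysisError(
                "scope must be 'overall' or 'rank:<r>' with a RankAssignment"
            )
        r = int(scope.split(":", 1)[1])
        wanted = [opt for opt, rk in ranks.rank_of.items() if rk == r]
        if not wanted:
            raise RunAnalysisError(f"no option holds rank {r}")
        lengths = runs.lengths[np.isin(runs.options, wanted)]
    if lengths.size == 0:
        raise RunAnalysisError(f"no runs in scope '{scope}'")
    s = _run_lengths_survival(lengths)
    s_next = np.append(s[1:], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(s > 0, (s - s_next) / np.where(s > 0, s, 1.0), np.nan)
    return RunDistribution(
        lengths=np.arange(1, s.size + 1),
        survival=s,
        hazard=h,
        scope=scope,
        n_runs=int(lengths.size),
    )


def shuffle_run_test(
    options: np.ndarray,
    n_shuffles: int = 999,
    seed: int | None = None,
    scope: str = "overall",
    ranks: RankAssignment | None = None,
) -> ShuffleTestResult:
    """Monte-Carlo test of run-length structure against exchangeability.

    The statistic is the sup-norm distance between the empirical run-length
    survival and the mean survival of ``n_shuffles`` frequency-preserving
    random shuffles.  Each shuffle's own statistic against the mean of the
    remaining ensemble forms the null; p = (1 + #{null ≥ observed}) /
    (n_shuffles + 1), so p is never 0 and never below 1/(n_shuffles+1).
    """
    if n_shuffles < 999:
        raise ValueError("n_shuffles must be >= 999")
    options = np.asarray(options)
    rng = np.random.default_rng(seed)

    def scoped_lengths(seq: np.ndarray) -> np.ndarray:
        runs = extract_runs(seq)
        if scope == "overall":
            return runs.lengths
        r = int(scope.split(":", 1)[1])
        wanted = [opt for opt, rk in ranks.rank_of.items() if rk == r]
        return runs.lengths[np.isin(runs.options, wanted)]

    emp_lengths = scoped_lengths(options)
    max_len = int(options.size)  # common grid long enough for any shuffle
    emp_s = _run_lengths_survival(emp_lengths, max_len)

    null_s = np.empty((n_shuffles, max_len))
    for k in range(n_shuffles):
        null_s[k] = _run_lengths_survival(scoped_lengths(rng.permutation(options)), max_len)
    mean_s = null_s.mean(axis=0)
    observed = float(np.max(np.abs(emp_s - mean_s)))
    # leave-one-out ensemble mean for each shuffle's own statistic
    loo_mean = (n_shuffles * mean_s[None, :] - null_s) / (n_shuffles - 1)
    null_stats = np.max(np.abs(null_s - loo_mean), axis=1)
    p = (1.0 + np.sum(null_stats >= observed)) / (n_shuffles + 1.0)
    return ShuffleTestResult(
        observed=observed,
        null=null_stats,
        p_value=float(p),
        n_shuffles=n_shuffles,
        seed=seed,
        scope=scope,
    )


def assign_ranks(options: np.ndarray) -> RankAssignment:
    """Rank options by descending total count; ties to first appearance.

    Also fits the log-linear rank curve (percentage vs log10 rank) when at
    least 3 ranks have positive counts.
    """
    options = np.asarray(options)
    if options.size == 0:
        raise RunAnalysisError("empty choice sequence")
    ids, first_idx, counts = np.unique(
        options, return_index=True, return_counts=True
    )
    order = sorted(range(ids.size), key=lambda i: (-counts[i], first_idx[i]))
    rank_of = {ids[i].item(): r + 1 for r, i in enumerate(order)}
    count_of = {ids[i].item(): int(counts[i]) for i in range(ids.size)}
    pct = np.array([100.0 * counts[i] / options.size for i in order])
    fit = fit_rank_loglinear(pct) if np.sum(pct > 0) >= 3 else None
    return RankAssignment(
        rank_of=rank_of, counts=count_of, percentages=pct, loglinear=fit
    )


def fit_rank_loglinear(percentages: np.ndarray) -> LogLinearFit:
    """OLS of choice percentage on log10(rank), with adjusted R².

    A strongly negative slope quantifies how sharply preference falls with
    rank (percentage roughly halving per rank corresponds to a slope near
    −70 per log10-unit for 4 options).
    """
    pct = np.asarray(percentages, dtype=float)
    pos = pct > 0
    if pos.sum() < 3:
        raise RunAnalysisError("need ≥ 3 ranks with positive percentages")
    ranks = np.arange(1, pct.size + 1)[pos]
    y = pct[pos]
    x = np.log10(ranks)
    coef = np.polyfit(x, y, 1)
    yhat = np.polyval(coef, x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = y.size, 1
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    return LogLinearFit(slope=float(coef[0]), intercept=float(coef[1]), adj_r2=float(adj))
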