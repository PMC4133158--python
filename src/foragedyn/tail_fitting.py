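"""Heavy-tail machinery for the bimodal inter-choice-interval distribution.

Short intervals (within activity bursts) follow a power law f(τ) ∝ τ^{−µ}
truncated at a crossover timescale τ₀; long intervals (the gaps between
bursts) follow a Weibull (stretched-exponential) law.  τ₀ is located as the
local minimum of the interval density between the two modes, the power-law
lower bound τ_min is selected by minimizing the Kolmogorov–Smirnov (KS)
distance between the fitted and empirical tail distributions, and fit
quality is scored by a parametric bootstrap of the KS statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerLawFit",
    "WeibullFit",
    "BimodalICIFit",
    "TailFitError",
    "survival_curve",
    "fit_powerlaw",
    "fit_weibull",
    "gof_bootstrap",
    "detect_tau0",
    "fit_bimodal",
]

MIN_TAIL_POINTS = 10


class TailFitError(ValueError):
    """Raised when a tail fit is undefined or the data are insufficient."""


# ---------------------------------------------------------------------------
# Empirical survival
# ---------------------------------------------------------------------------

def survival_curve(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function S(x) = P(X >= x).

    Returns ``(support, survival)`` where support is the sorted unique
    values; S is right-continuous with S(min) = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise TailFitError("survival of an empty sample is undefined")
    support, counts = np.unique(x, return_counts=True)
    # P(X >= support[i]) = (count of values >= support[i]) / n
    ge = counts[::-1].cumsum()[::-1]
    return support, ge / x.size


# ---------------------------------------------------------------------------
# Power law
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """Truncated or untruncated power-law fit f(x) ∝ x^{−µ} on [τ_min, τ_0]."""

    mu: float
    tau_min: float
    tau_0: float | None
    D: float
    n_tail: int
    p_gof: float | None = None

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a = self.tau_min
        if self.tau_0 is None:
            c = 1.0 - (x / a) ** (1.0 - self.mu)
        else:
            b = self.tau_0
            e = 1.0 - self.mu
            c = (a**e - np.clip(x, a, b) ** e) / (a**e - b**e)
        return np.clip(c, 0.0, 1.0)

    def survival(self, x: np.ndarray) -> np.ndarray:
        return 1.0 - self.cdf(x)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return _powerlaw_inverse_cdf(
            rng.random(n), self.mu, self.tau_min, self.tau_0
        )


def _powerlaw_inverse_cdf(
    u: np.ndarray, mu: float, tau_min: float, tau_0: float | None
) -> np.ndarray:
    e = 1.0 - mu
    if tau_0 is None:
        return tau_min * (1.0 - u) ** (1.0 / e)
    return (tau_min**e - u * (tau_min**e - tau_0**e)) ** (1.0 / e)


def _powerlaw_mle(x: np.ndarray, tau_min: float, tau_0: float | None) -> float:
    """Maximum-likelihood exponent µ̂ for data on [tau_min, tau_0]."""
    n = x.size
    slog = float(np.sum(np.log(x / tau_min)))
    if tau_0 is None:
        # closed form (Hill estimator): µ̂ = 1 + n / Σ ln(x_i/τ_min)
        return 1.0 + n / slog

    la, lb = np.log(tau_min), np.log(tau_0)

    def negloglik(mu: float) -> float:
        e = 1.0 - mu
        # log normalizing constant of x^{-mu} on [a, b]
        log_z = np.log((np.exp(e * lb) - np.exp(e * la)) / e) if abs(e) > 1e-12 else np.log(lb - la)
        return n * log_z + mu * (slog + n * la)

    res = optimize.minimize_scalar(
        negloglik, bounds=(1.0 + 1e-6, 6.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def _ks_distance(x_tail: np.ndarray, fit: PowerLawFit) -> float:
    xs = np.sort(x_tail)
    n = xs.size
    cdf = fit.cdf(xs)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(cdf - ecdf_hi)), np.max(np.abs(cdf - ecdf_lo))))


def fit_powerlaw(
    values: np.ndarray,
    tau_min: float | str = "scan",
    tau_0: float | None = None,
    max_scan_candidates: int = 100,
) -> PowerLawFit:
    """Fit a power law by MLE, selecting τ_min by the KS criterion if asked.

    With ``tau_min="scan"`` every unique value (subsampled to at most
    ``max_scan_candidates`` quantile-spaced candidates) is tried as the lower
    bound and the one minimizing the KS distance D between the fitted and
    empirical tail distributions is kept; ties break toward the smaller
    τ_min (more data).  With a fixed untruncated ``tau_min`` the exponent has
    the closed form µ̂ = 1 + n/Σ ln(x_i/τ_min).
    """
    x = np.asarray(values, dtype=float)
    x = x[x > 0]
    if tau_0 is not None:
        x = x[x <= tau_0]

    if tau_min != "scan":
        a = float(tau_min)
        tail = x[x >= a]
        if tail.size < MIN_TAIL_POINTS:
            raise TailFitError(
                f"only {tail.size} values ≥ τ_min={a}; need {MIN_TAIL_POINTS}"
            )
        mu = _powerlaw_mle(tail, a, tau_0)
        f = PowerLawFit(mu=mu, tau_min=a, tau_0=tau_0, D=0.0, n_tail=tail.size)
        f.D = _ks_distance(tail, f)
        return f

    candidates = np.unique(x)
    candidates = candidates[: max(1, candidates.size - MIN_TAIL_POINTS + 1)]
    if candidates.size > max_scan_candidates:
        idx = np.unique(
            np.linspace(0, candidates.size - 1, max_scan_candidates).astype(int)
        )
        candidates = candidates[idx]

    best: PowerLawFit | None = None
    for a in candidates:
        tail = x[x >= a]
        if tail.size < MIN_TAIL_POINTS:
            continue
        mu = _powerlaw_mle(tail, float(a), tau_0)
        f = PowerLawFit(mu=mu, tau_min=float(a), tau_0=tau_0, D=0.0, n_tail=tail.size)
        f.D = _ks_distance(tail, f)
        if best is None or f.D < best.D:  # strict: ties keep smaller τ_min
            best = f
    if best is None:
        raise TailFitError("no τ_min candidate leaves enough tail points")
    return best


# ---------------------------------------------------------------------------
# Weibull
# ---------------------------------------------------------------------------

@dataclass
class WeibullFit:
    """Weibull fit with scale λ and shape γ; survival exp(−(x/λ)^γ)."""

    lam: float
    gamma: float
    n: int
    p_gof: float | None = None
    left_trunc: float | None = None

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return stats.weibull_min.cdf(x, self.gamma, scale=self.lam)

    def survival(self, x: np.ndarray) -> np.ndarray:
        return stats.weibull_min.sf(x, self.gamma, scale=self.lam)

    def conditional_cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF conditioned on x ≥ left_trunc (the tail the fit saw)."""
        if self.left_trunc is None:
            return self.cdf(x)
        s0 = float(self.survival(np.array([self.left_trunc]))[0])
        return np.clip(1.0 - self.survival(x) / s0, 0.0, 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.left_trunc is None:
            return self.lam * rng.weibull(self.gamma, n)
        s0 = np.exp(-((self.left_trunc / self.lam) ** self.gamma))
        u = rng.random(n) * s0
        return self.lam * (-np.log(u)) ** (1.0 / self.gamma)


def fit_weibull(values: np.ndarray, left_trunc: float | None = None) -> WeibullFit:
    """Maximum-likelihood Weibull fit (location fixed at 0).

    With ``left_trunc`` the likelihood is conditioned on x ≥ left_trunc,
    i.e. each density term is divided by the survival at the truncation
    point — appropriate when the sample is the tail of a split
    distribution, as in the bimodal interval fit.
    """
    x = np.asarray(values, dtype=float)
    x = x[x > 0]
    if x.size < MIN_TAIL_POINTS:
        raise TailFitError(f"need at least {MIN_TAIL_POINTS} positive values")
    if np.all(x == x[0]):
        raise TailFitError("degenerate data: all values equal")
    if left_trunc is None:
        shape, _, scale = stats.weibull_min.fit(x, floc=0)
        return WeibullFit(lam=float(scale), gamma=float(shape), n=x.size)

    L = float(left_trunc)
    logx = np.log(x)
    n = x.size

    def negloglik(theta: np.ndarray) -> float:
        lam, gam = np.exp(theta)
        z = (x / lam) ** gam
        ll = (
            n * (np.log(gam) - gam * np.log(lam))
            + (gam - 1.0) * logx.sum()
            - z.sum()
            + n * (L / lam) ** gam  # − n·log S(L), S(L)=exp(−(L/λ)^γ)
        )
        return -ll

    x0 = np.log([max(np.mean(x), L), 1.0])
    res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    lam, gam = np.exp(res.x)
    return WeibullFit(lam=float(lam), gamma=float(gam), n=n, left_trunc=L)


# ---------------------------------------------------------------------------
# Bootstrap goodness of fit
# ---------------------------------------------------------------------------

def _weibull_ks(x: np.ndarray, fit: WeibullFit) -> float:
    return float(stats.kstest(x, fit.conditional_cdf).statistic)


def gof_bootstrap(
    fit: PowerLawFit | WeibullFit,
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Parametric-bootstrap p-value for the KS goodness of fit.

    Simulates ``n_boot`` samples of matched size from the fitted model,
    refits each, and reports the fraction whose KS statistic is at least the
    observed one.  Large p means the model is a plausible generator of the
    data; p near 0 rejects it.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    if isinstance(fit, PowerLawFit):
        tail = x[x >= fit.tau_min]
        if fit.tau_0 is not None:
            tail = tail[tail <= fit.tau_0]
        d_obs = _ks_distance(tail, fit)
        exceed = 0
        for _ in range(n_boot):
            sim = fit.sample(tail.size, rng)
            mu_b = _powerlaw_mle(sim, fit.tau_min, fit.tau_0)
            f_b = PowerLawFit(mu_b, fit.tau_min, fit.tau_0, 0.0, sim.size)
            if _ks_distance(sim, f_b) >= d_obs:
                exceed += 1
    else:
        d_obs = _weibull_ks(x, fit)
        exceed = 0
        for _ in range(n_boot):
            sim = fit.sample(x.size, rng)
            f_b = fit_weibull(sim, left_trunc=fit.left_trunc)
            if _weibull_ks(sim, f_b) >= d_obs:
                exceed += 1
    p = exceed / n_boot
    fit.p_gof = p
    return p


# ---------------------------------------------------------------------------
# Crossover detection and the bimodal piecewise fit
# ---------------------------------------------------------------------------

def detect_tau0(
    intervals,
    search: tuple[float, float] = (50.0, 1000.0),
    bins_per_decade: int = 25,
    smooth_bins: int = 3,
) -> float:
    """Crossover timescale τ₀: local density minimum between the two modes.

    The interval density is estimated on logarithmically spaced bins
    (``bins_per_decade``) and smoothed with a short moving average; τ₀ is
    the abscissa of the lowest interior local minimum inside ``search``
    (default 50–1000 s, between the burst mode and the circadian-gap mode).
    If the density shows no interior minimum at the requested bandwidth the
    moving average is widened twice (by 2 bins each time) before giving up —
    small samples need more smoothing, while a genuinely unimodal density
    (e.g. exponential intervals) stays monotone at every bandwidth and
    raises :class:`TailFitError`.
    """
    x = np.asarray(getattr(intervals, "intervals", intervals), dtype=float)
    lo, hi = search
    if x.min() >= lo or x.max() <= hi:
        raise TailFitError(
            f"intervals do not span the search range [{lo}, {hi}] s"
        )
    edges = np.logspace(
        np.log10(x.min()), np.log10(x.max()),
        int(np.log10(x.max() / x.min()) * bins_per_decade) + 2,
    )
    counts, edges = np.histogram(x, bins=edges)
    raw_density = counts / np.diff(edges) / x.size
    centers = np.sqrt(edges[:-1] * edges[1:])
    idx = np.flatnonzero((centers >= lo) & (centers <= hi))

    for sb in (smooth_bins, smooth_bins + 2, smooth_bins + 4):
        density = raw_density
        if sb > 1:
            kernel = np.ones(sb) / sb
            density = np.convolve(raw_density, kernel, mode="same")
        # interior local minima of the smoothed density, within the range
        minima = [
            i for i in idx
            if 0 < i < density.size - 1
            and density[i] <= density[i - 1]
            and density[i] <= density[i + 1]
            and (density[i] < density[i - 1] or density[i] < density[i + 1])
        ]
        if minima:
            best = min(minima, key=lambda i: density[i])
            return float(centers[best])
    raise TailFitError(
        "no interior density minimum in the search range: "
        "interval distribution is not bimodal there"
    )


@dataclass
class BimodalICIFit:
    """Piecewise power-law (head) + Weibull (tail) interval distribution.

    The composite survival is a mixture continuous at τ₀:
    S(t) = w·S_head(t) + (1−w) below τ₀ and (1−w)·S_wb(t)/S_wb(τ₀) above,
    where w is the fraction of intervals below τ₀.
    """

    tau_0: float
    head: PowerLawFit
    tail: WeibullFit
    w_head: float
    cycle: str = "overall"
    n: int = 0

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        below = t < self.tau_0
        s = np.empty_like(t)
        s[below] = self.w_head * self.head.survival(t[below]) + (1.0 - self.w_head)
        s_wb_tau0 = self.tail.survival(np.array([self.tau_0]))[0]
        s[~below] = (
            (1.0 - self.w_head) * self.tail.survival(t[~below]) / s_wb_tau0
            if s_wb_tau0 > 0
            else 0.0
        )
        return np.clip(s, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "cycle": self.cycle,
            "tau_min": self.head.tau_min,
            "tau_0": self.tau_0,
            "mu": self.head.mu,
            "p_powerlaw": self.head.p_gof,
            "lambda": self.tail.lam,
            "gamma": self.tail.gamma,
            "p_weibull": self.tail.p_gof,
            "w_head": self.w_head,
            "n": self.n,
        }


def fit_bimodal(
    icis,
    cycle: str = "overall",
    tau_0: float | None = None,
    search: tuple[float, float] = (50.0, 1000.0),
    tau_min: float | str = "scan",
) -> BimodalICIFit:
    """Fit the piecewise power-law/Weibull interval distribution.

    τ₀ defaults to crossover detection on the full (overall) interval set so
    that light/dark fits share one crossover; pass ``tau_0`` to override.
    The head is a τ₀-truncated power law on [τ_min, τ₀) with τ_min chosen by
    KS scan; the tail is a Weibull MLE on intervals ≥ τ₀.
    """
    from .temporal_stats import ICISeries  # local: avoid import cycle at load

    if isinstance(icis, ICISeries):
        all_x = icis.intervals
        x = icis.select(cycle)
    else:
        all_x = np.asarray(icis, dtype=float)
        x = all_x
        if cycle != "overall":
            raise TailFitError("cycle selection requires an ICISeries input")
    if tau_0 is None:
        tau_0 = detect_tau0(all_x, search=search)

    head_x = x[x < tau_0]
    tail_x = x[x >= tau_0]
    if head_x.size < MIN_TAIL_POINTS or tail_x.size < MIN_TAIL_POINTS:
        raise TailFitError(
            f"too few intervals on one side of τ₀={tau_0:.1f}s "
            f"(head {head_x.size}, tail {tail_x.size})"
        )
    head = fit_powerlaw(head_x, tau_min=tau_min, tau_0=tau_0)
    tail = fit_weibull(tail_x, left_trunc=tau_0)
    # The truncated MLE extrapolates the unobserved region below τ₀; when it
    # places most of the fitted mass there (observed tail < half the fitted
    # distribution) the scale/shape are unconstrained by data, so fall back
    # to the plain MLE on the tail values.
    if tail.survival(np.array([tau_0]))[0] < 0.5:
        tail = fit_weibull(tail_x)
    # weight: fraction of modelled intervals (≥ τ_min) that fall below τ₀
    n_model = int(np.sum(x >= head.tau_min))
    w_head = float(np.sum((x >= head.tau_min) & (x < tau_0)) / n_model)
    return BimodalICIFit(
        tau_0=float(tau_0), head=head, tail=tail, w_head=w_head,
        cycle=cycle, n=n_model,
    )
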