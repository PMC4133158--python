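"""Dual-control model of what is chosen: goal-directed + habitual systems.

The goal-directed controller carries an action value Q_i updated by a
temporal-difference rule — the chosen option moves toward its reward value
R_c with learning rate α_c, every unchosen option decays toward 0 with
rate α_u.  Reward values are obtained deductively from the generalized
matching law, R_i ∝ rate_i^{1/a} with sensitivity a, normalized to max 1.
The habitual controller carries a leaky integration of the choice history,
H_i(t) = Σ_τ e^{−τ/κ} c_i(t−τ), which implements preferential attachment:
options chosen recently and often are valued more, irrespective of
outcome.  Choice probabilities combine both systems through a dual
softmax, P_i ∝ exp(β_G Q_i + β_H H_i).

Nested variants (Goal_c+u, Goal_c, Habit, Goal_c+Habit) silence one system
or the unchosen-decay term; maximum-likelihood fits are compared by BIC,
pseudo-r² against the random-choice baseline, and likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats

__all__ = [
    "DualControlParams",
    "ModelFit",
    "VARIANTS",
    "habit_trajectory",
    "reward_values",
    "goal_step",
    "choice_probabilities",
    "sequence_nll",
    "fit_choice_model",
    "compare_models",
    "simulate_choices",
]

# variant -> (uses goal system, uses unchosen decay, uses habit system)
VARIANTS: dict[str, tuple[bool, bool, bool]] = {
    "dual": (True, True, True),
    "goal_cu": (True, True, False),
    "goal_c": (True, False, False),
    "habit": (False, False, True),
    "goal_c_habit": (True, False, True),
}

# free parameters per variant (order fixed: alpha_c, alpha_u, a, kappa, beta_G, beta_H)
_FREE: dict[str, tuple[str, ...]] = {
    "dual": ("alpha_c", "alpha_u", "a", "kappa", "beta_G", "beta_H"),
    "goal_cu": ("alpha_c", "alpha_u", "a", "beta_G"),
    "goal_c": ("alpha_c", "a", "beta_G"),
    "habit": ("kappa", "beta_H"),
    "goal_c_habit": ("alpha_c", "a", "kappa", "beta_G", "beta_H"),
}

_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_c": (1e-4, 1.0),
    "alpha_u": (1e-4, 1.0),
    "a": (0.2, 10.0),
    "kappa": (0.5, 500.0),
    "beta_G": (0.0, 50.0),
    "beta_H": (0.0, 50.0),
}

# declared nestings for likelihood-ratio tests (full -> nested)
NESTINGS: dict[str, tuple[str, ...]] = {
    "dual": ("goal_cu", "goal_c", "habit", "goal_c_habit"),
    "goal_cu": ("goal_c",),
    "goal_c_habit": ("goal_c", "habit"),
}


@dataclass
class DualControlParams:
    """Parameters of the dual-control choice model (see module docstring)."""

    alpha_c: float = 0.5
    alpha_u: float = 0.3
    a: float = 0.8
    kappa: float = 60.0
    beta_G: float = 1.0
    beta_H: float = 0.03
    variant: str = "dual"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant '{self.variant}'")
        if not (0.0 <= self.alpha_c <= 1.0 and 0.0 <= self.alpha_u <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("κ must be positive")
        if self.a <= 0:
            raise ValueError("matching sensitivity a must be positive")
        if self.beta_G < 0 or self.beta_H < 0:
            raise ValueError("inverse temperatures must be ≥ 0")

    @property
    def k(self) -> int:
        """Free-parameter count of the variant (enters the BIC)."""
        return len(_FREE[self.variant])

    def masked(self) -> "DualControlParams":
        """Parameters with inactive systems silenced per the variant."""
        use_goal, use_decay, use_habit = VARIANTS[self.variant]
        return replace(
            self,
            beta_G=self.beta_G if use_goal else 0.0,
            alpha_u=self.alpha_u if use_decay else 0.0,
            beta_H=self.beta_H if use_habit else 0.0,
        )

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FREE[self.variant]])

    @classmethod
    def from_vector(cls, x: np.ndarray, variant: str) -> "DualControlParams":
        kw = dict(zip(_FREE[variant], map(float, x)))
        return cls(variant=variant, **kw)


def reward_values(rates: np.ndarray, a: float) -> np.ndarray:
    """Reward values from mean choice rates via matching-law inversion.

    The generalized matching law states choice ratios follow reward-value
    ratios raised to the sensitivity a; inverting, R_i ∝ rate_i^{1/a},
    normalized so the best option has R = 1.
    """
    if a <= 0:
        raise ValueError("matching sensitivity a must be positive")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0) or not np.isclose(rates.sum(), 1.0):
        raise ValueError("rates must be non-negative and sum to 1")
    r = rates ** (1.0 / a)
    return r / r.max()


def habit_trajectory(options: np.ndarray, kappa: float, n_options: int | None = None) -> np.ndarray:
    """Habit values H_i(t) = Σ_{τ=1}^{t−1} e^{−τ/κ} c_i(t−τ) for every trial.

    Computed by the equivalent leaky-integrator recursion
    H(t+1) = e^{−1/κ} (H(t) + c(t)) with H(1) = 0.  Returns an
    (n_trials, n_options) array of pre-choice habit values.
    """
    if kappa <= 0:
        raise ValueError("κ must be positive")
    options = np.asarray(options, dtype=np.int64)
    n_opt = n_options or int(options.max()) + 1
    decay = np.exp(-1.0 / kappa)
    H = np.zeros((options.size, n_opt))
    for t in range(options.size - 1):
        H[t + 1] = decay * H[t]
        H[t + 1, options[t]] += decay
    return H


def goal_step(
    Q: np.ndarray, choice: int, R_c: float, alpha_c: float, alpha_u: float
) -> np.ndarray:
    """One TD update: chosen toward R_c, unchosen decayed toward 0."""
    Q = np.asarray(Q, dtype=float).copy()
    delta_c = R_c - Q[choice]
    mask = np.ones(Q.size, dtype=bool)
    mask[choice] = False
    Q[mask] += alpha_u * (0.0 - Q[mask])
    Q[choice] += alpha_c * delta_c
    return Q


def choice_probabilities(Q: np.ndarray, H: np.ndarray, beta_G: float, beta_H: float) -> np.ndarray:
    """Dual softmax P_i ∝ exp(β_G Q_i + β_H H_i), max-subtracted for stability."""
    z = beta_G * np.asarray(Q, float) + beta_H * np.asarray(H, float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@njit(cache=True)
def _nll_kernel(
    choices: np.ndarray,
    R: np.ndarray,
    n_opt: int,
    alpha_c: float,
    alpha_u: float,
    kappa: float,
    beta_G: float,
    beta_H: float,
    use_goal: bool,
    use_habit: bool,
) -> float:  # pragma: no cover - exercised through sequence_nll
    decay = np.exp(-1.0 / kappa)
    Q = np.zeros(n_opt)
    H = np.zeros(n_opt)
    z = np.empty(n_opt)
    nll = 0.0
    for t in range(choices.size):
        zmax = -1e300
        for i in range(n_opt):
            z[i] = beta_G * Q[i] + beta_H * H[i]
            if z[i] > zmax:
                zmax = z[i]
        denom = 0.0
        for i in range(n_opt):
            denom += np.exp(z[i] - zmax)
        c = choices[t]
        nll -= z[c] - zmax - np.log(denom)
        if use_goal:
            for i in range(n_opt):
                if i == c:
                    Q[i] += alpha_c * (R[c] - Q[i])
                else:
                    Q[i] += alpha_u * (0.0 - Q[i])
        if use_habit:
            for i in range(n_opt):
                H[i] = decay * H[i]
            H[c] += decay
    return nll


def sequence_nll(
    options: np.ndarray,
    params: DualControlParams,
    R: np.ndarray | None = None,
    n_options: int = 4,
) -> float:
    """Negative log-likelihood of a choice sequence under the model.

    A forward pass over trials updates H (and Q for goal variants) and
    accumulates −ln P of each observed choice; inactive systems are masked
    (their β forced to 0 and updates skipped).  When ``R`` is omitted it is
    derived from the sequence's own mean choice rates via
    :func:`reward_values`.
    """
    options = np.asarray(options, dtype=np.int64)
    p = params.masked()
    use_goal, _, use_habit = VARIANTS[params.variant]
    if R is None:
        rates = np.bincount(options, minlength=n_options) / options.size
        R = reward_values(rates, p.a)
    R = np.asarray(R, dtype=float)
    return float(
        _nll_kernel(
            options, R, n_options,
            p.alpha_c, p.alpha_u, p.kappa, p.beta_G, p.beta_H,
            use_goal, use_habit,
        )
    )


@dataclass
class ModelFit:
    """Result of a maximum-likelihood dual-control fit."""

    params: DualControlParams
    nll: float
    k: int
    n: int
    n_options: int = 4
    restarts: int = 1
    seed: int | None = None
    converged: bool = True

    @property
    def bic(self) -> float:
        return 2.0 * self.nll + self.k * np.log(self.n)

    @property
    def pseudo_r2(self) -> float:
        """(R − L)/R against the random-choice baseline R = N ln(1/n_options)."""
        r = self.n * np.log(1.0 / self.n_options)
        return float((r - (-self.nll)) / r)

    @property
    def variant(self) -> str:
        return self.params.variant


def fit_choice_model(
    options: np.ndarray,
    variant: str = "dual",
    restarts: int = 20,
    seed: int | None = None,
    n_options: int = 4,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit a dual-control variant by bounded multi-start minimization.

    Mean choice rates of the data itself feed the matching-law reward
    values (re-derived at each candidate a, since R depends on a); L-BFGS-B
    from ``restarts`` uniform-random starting points within the bounds, the
    best optimum kept.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant '{variant}'")
    options = np.asarray(options, dtype=np.int64)
    rng = np.random.default_rng(seed)
    free = _FREE[variant]
    bounds = [_BOUNDS[f] for f in free]
    rates = np.bincount(options, minlength=n_options) / options.size

    def objective(x: np.ndarray) -> float:
        p = DualControlParams.from_vector(x, variant).masked()
        use_goal, _, use_habit = VARIANTS[variant]
        R = reward_values(rates, p.a) if use_goal else np.zeros(n_options)
        return _nll_kernel(
            options, R, n_options,
            p.alpha_c, p.alpha_u, p.kappa, p.beta_G, p.beta_H,
            use_goal, use_habit,
        )

    # scale-type parameters get log-uniform starting points so multistart
    # covers small gains and short/long memories evenly
    _log_scale = {"a", "kappa", "beta_G", "beta_H"}

    def draw_start() -> np.ndarray:
        x0 = np.empty(len(free))
        for j, (f, (lo, hi)) in enumerate(zip(free, bounds)):
            if f in _log_scale:
                lo_ = max(lo, 1e-3)
                x0[j] = np.exp(rng.uniform(np.log(lo_), np.log(hi)))
            else:
                x0[j] = rng.uniform(lo, hi)
        return x0

    best = None
    n_ok = 0
    for _ in range(restarts):
        x0 = draw_start()
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "maxiter": 500},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError("optimizer failed on every restart")
    params = DualControlParams.from_vector(best.x, variant)
    return ModelFit(
        params=params,
        nll=float(best.fun),
        k=len(free),
        n=options.size,
        n_options=n_options,
        restarts=restarts,
        seed=seed,
        converged=bool(best.success) and n_ok == restarts,
    )


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Model-comparison table: −LL, k, BIC, ΔBIC, pseudo-r², nested LRTs.

    Likelihood-ratio tests use Λ = 2(LL_full − LL_nested) with df = Δk and a
    chi-square p-value, only for the declared nestings; requesting a
    non-nested pair raises.
    """
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits must be on the same data (equal N)")
    by_variant = {f.variant: f for f in fits}
    rows = []
    best_bic = min(f.bic for f in fits)
    for f in fits:
        row = {
            "variant": f.variant,
            "nll": f.nll,
            "k": f.k,
            "bic": f.bic,
            "delta_bic": f.bic - best_bic,
            "pseudo_r2": f.pseudo_r2,
            "lrt_vs": None,
            "lrt_stat": None,
            "lrt_df": None,
            "lrt_p": None,
        }
        # LRT of each nested fit against the fullest fitted model containing it
        for full, nested_set in NESTINGS.items():
            if full in by_variant and f.variant in nested_set:
                stat, df, p = lrt(by_variant[full], f)
                row.update(lrt_vs=full, lrt_stat=stat, lrt_df=df, lrt_p=p)
                break
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    table["winner"] = table["bic"] == table["bic"].min()
    return table


def lrt(full: ModelFit, nested: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested fit against the full fit."""
    if nested.variant not in NESTINGS.get(full.variant, ()):
        raise ValueError(
            f"'{nested.variant}' is not a declared nested model of '{full.variant}'"
        )
    stat = 2.0 * (nested.nll - full.nll)
    df = full.k - nested.k
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return float(stat), df, p


def simulate_choices(
    params: DualControlParams,
    R: np.ndarray,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    n_options: int = 4,
) -> np.ndarray:
    """Generate a choice sequence from the model by forward sampling."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params.masked()
    use_goal, _, use_habit = VARIANTS[params.variant]
    R = np.asarray(R, dtype=float)
    decay = np.exp(-1.0 / p.kappa)
    Q = np.zeros(n_options)
    H = np.zeros(n_options)
    out = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        prob = choice_probabilities(Q, H, p.beta_G, p.beta_H)
        c = int(rng.choice(n_options, p=prob))
        out[t] = c
        if use_goal:
            Q = goal_step(Q, c, R[c], p.alpha_c, p.alpha_u)
        if use_habit:
            H = decay * H
            H[c] += decay
    return out
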