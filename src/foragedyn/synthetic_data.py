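"""Synthetic foraging datasets with known ground truth.

Composes the dual-state timing simulator with the dual-control choice
simulator to emulate a two-week, four-option free-foraging log: bursty
active bouts with power-law intra-bout intervals, circadian-modulated
inter-bout gaps, a rank-biased choice distribution, and persistent
(heavy-tailed run) choice sequences.  Timing and choice are independent
modules over the same event stream — choice-model trials map 1:1 onto
timing events, with no timing-choice coupling.

Also provides small analytic fixtures (homogeneous Poisson, periodic,
alternating, truncated power-law, bimodal-interval) used to pin down the
limiting values of the descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dual_control import DualControlParams, reward_values, simulate_choices
from .dual_state import DualStateParams, sample_truncated_powerlaw, simulate_dual_state
from .event_model import EventLog

__all__ = ["SyntheticConfig", "generate_dataset", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("hpp", "periodic", "alternating", "powerlaw", "bimodal_ici")

DEFAULT_RATES = np.array([0.50, 0.25, 0.15, 0.10])


@dataclass
class SyntheticConfig:
    """Full specification of a reproducible synthetic dataset.

    Defaults emulate the study conditions: 14 days, 4 options with a
    rank-biased target choice distribution (50/25/15/10 %), dual-state
    timing at the recovered parameter magnitudes, and a dual-control choice
    process with both systems active.
    """

    dual_state: DualStateParams = field(default_factory=DualStateParams)
    dual_control: DualControlParams = field(default_factory=DualControlParams)
    target_rates: np.ndarray = field(default_factory=lambda: DEFAULT_RATES.copy())
    days: float = 14.0
    option_labels: tuple[str, ...] = ("chocolate", "coffee", "banana", "cinnamon")
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        kw = dict(d)
        if "dual_state" in kw:
            kw["dual_state"] = DualStateParams(**kw["dual_state"])
        if "dual_control" in kw:
            kw["dual_control"] = DualControlParams(**kw["dual_control"])
        if "target_rates" in kw:
            kw["target_rates"] = np.asarray(kw["target_rates"], dtype=float)
        kw.pop("options", None)
        return cls(**kw)

    @property
    def true_reward_values(self) -> np.ndarray:
        return reward_values(self.target_rates, self.dual_control.a)


def generate_dataset(config: SyntheticConfig) -> EventLog:
    """Generate one synthetic log: dual-state timestamps × dual-control options."""
    rng = np.random.default_rng(config.seed)
    timing = simulate_dual_state(
        config.dual_state, duration=config.days * 86400.0, seed=rng
    )
    options = simulate_choices(
        config.dual_control,
        R=config.true_reward_values,
        n_trials=timing.n_events,
        seed=rng,
        n_options=len(config.option_labels),
    )
    return EventLog(
        timestamps=timing.timestamps,
        options=options,
        schedule=config.dual_state.schedule,
        duration=timing.duration,
        labels=dict(enumerate(config.option_labels)),
    )


def generate_fixture(
    kind: str,
    n: int = 1000,
    seed: int | None = None,
    **params,
) -> np.ndarray:
    """Analytic interval fixtures with known limiting statistics.

    kind:
      - ``hpp``: i.i.d. exponential intervals (burstiness B → 0);
        ``scale`` (mean, default 1.0)
      - ``periodic``: constant intervals (B = −1 exactly); ``value``
      - ``alternating``: two-valued alternation (memory M = −1);
        ``low``/``high``
      - ``powerlaw``: truncated power-law intervals; ``mu``, ``tau_min``,
        ``tau_0``
      - ``bimodal_ici``: mixture matching the dual-state marginal —
        power-law bursts plus Weibull-distributed gaps; ``w_head``,
        ``mu``, ``tau_min``, ``tau_0``, ``lam``, ``gamma``
    """
    rng = np.random.default_rng(seed)
    if kind == "hpp":
        return rng.exponential(params.get("scale", 1.0), n)
    if kind == "periodic":
        return np.full(n, float(params.get("value", 10.0)))
    if kind == "alternating":
        low, high = params.get("low", 1.0), params.get("high", 100.0)
        out = np.empty(n)
        out[0::2] = low
        out[1::2] = high
        return out
    if kind == "powerlaw":
        return sample_truncated_powerlaw(
            params.get("mu", 2.0),
            params.get("tau_min", 10.0),
            params.get("tau_0", 500.0),
            n,
            rng,
        )
    if kind == "bimodal_ici":
        w = params.get("w_head", 0.85)
        lam, gamma = params.get("lam", 4160.0), params.get("gamma", 0.91)
        tau_0 = params.get("tau_0", 500.0)
        n_head = rng.binomial(n, w)
        head = sample_truncated_powerlaw(
            params.get("mu", 2.0), params.get("tau_min", 10.0), tau_0, n_head, rng
        )
        # gap component: Weibull conditioned on exceeding τ_0 (inverse CDF)
        s0 = np.exp(-((tau_0 / lam) ** gamma))
        u = rng.random(n - n_head) * s0
        tail = lam * (-np.log(u)) ** (1.0 / gamma)
        out = np.concatenate([head, tail])
        rng.shuffle(out)
        return out
    raise ValueError(f"unknown fixture kind '{kind}'; choose from {FIXTURE_KINDS}")
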