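# foragedyn

Temporal and sequential dynamics of free foraging decisions.

`foragedyn` analyses continuous, multi-day choice logs — one timestamped
record per choice among a small set of options (e.g. a rat pressing one of
four flavored-pellet levers for two weeks under a 12 h/12 h light/dark
cycle) — and answers two questions: **when** does the animal act, and
**what** does it choose?

It is written for behavioral neuroscientists and computational ethologists
who study self-paced, closed-economy foraging and need a tested pipeline
for the descriptive statistics and for generative-model fitting of such
logs.

## What it computes

**When (temporal dynamics).** Inter-choice intervals (ICIs) of free
foraging are *bursty*: the burstiness index

    B = (σ_τ − m_τ) / (σ_τ + m_τ)

(m_τ, σ_τ the ICI mean and population SD) approaches 1 for bursty trains,
0 for a homogeneous Poisson process, −1 for a metronome; the memory
coefficient M is the lag-1 correlation of consecutive ICIs.  The ICI
distribution is bimodal: below a crossover timescale τ₀ (the local minimum
of the ICI density, sought between 50 and 1000 s) intervals follow a
truncated power law f(τ) ∝ τ^(−µ), above it the burst-separating gaps are
Weibull, S(τ) = exp(−(τ/λ)^γ).  Fitting uses Clauset-style maximum
likelihood with KS-minimizing lower-bound selection and parametric
bootstrap goodness of fit.  A generative **dual-state model** reproduces
this structure: an active state emits power-law ICIs and exits with
probability ξ after each choice; the inactive state ends at the first
arrival of a non-homogeneous Poisson process whose rate
ρ(t) ∝ ρ₀ · P_A(h(t))^b is modulated by the hour-of-day profile P_A of
activity onsets — the circadian rhythm.  Free parameters are estimated by
least-area matching of empirical and simulated log-log ICI survival
curves.

**What (sequential dynamics).** Choices are rank-biased (percentage falls
linearly in log rank) and persistent: runs of identical choices have heavy
tails and a hazard of ending that *decreases* with run length
(preferential attachment), which Monte-Carlo shuffle tests detect against
frequency-matched null ensembles.  A **dual-control model** captures both
features: a goal-directed system updates the chosen option's value toward
its reward value R_c (learning rate α_c) and decays unchosen values
(α_u), with R_i ∝ rate_i^(1/a) from the generalized matching law; a
habitual system carries a leaky integration of choice history,
H_i(t) = Σ_τ e^(−τ/κ) c_i(t−τ).  Both feed a softmax,
P_i ∝ exp(β_G Q_i + β_H H_i).  Nested variants (Goal_c+u, Goal_c, Habit,
Goal_c+Habit) are fitted by multistart maximum likelihood and compared by
BIC = 2·NLL + k·ln N, pseudo-r² against a random-choice baseline, and
likelihood-ratio tests.

A synthetic-data module composes both generative models into full
datasets with known ground truth, so every stage of the pipeline is
testable without animal data.

## Worked example

```python
import numpy as np
from foragedyn import (SyntheticConfig, generate_dataset, interchoice_intervals,
    burstiness, memory_coefficient, autocorrelogram_period, fit_bimodal,
    assign_ranks, shuffle_run_test, fit_choice_model, compare_models)

log = generate_dataset(SyntheticConfig(seed=1))   # 14 days, 4 options
icis = interchoice_intervals(log)
print(f"B = {burstiness(icis):.3f}   M = {memory_coefficient(icis):.3f}")
print(f"period: {autocorrelogram_period(log, 1.0).period:.1f} h")
d = fit_bimodal(icis).to_dict()
print(f"tau0 = {d['tau_0']:.0f} s  mu = {d['mu']:.2f}  "
      f"lambda = {d['lambda']:.0f} s  gamma = {d['gamma']:.2f}")
ranks = assign_ranks(log.options)
print("choice % by rank:", np.round(ranks.percentages, 1))
print("shuffle test p =", shuffle_run_test(log.options, 999, seed=0).p_value)
fits = [fit_choice_model(log.options, v, restarts=10, seed=i)
        for i, v in enumerate(["dual", "goal_cu", "habit"])]
print(compare_models(fits)[["variant", "nll", "k", "bic", "pseudo_r2"]])
```

prints

```
B = 0.800   M = -0.005
period: 24.0 h
tau0 = 932 s  mu = 1.98  lambda = 5653 s  gamma = 0.79
choice % by rank: [57.6 15.2 13.8 13.4]
shuffle test p = 0.002
variant     nll  k     bic  pseudo_r2
   dual 4249.41  6 8548.27       0.19
goal_cu 4258.88  4 8550.73       0.19
  habit 4303.40  2 8623.29       0.18
```

Reading the output: the timing is strongly bursty (B = 0.80) with little
interval-to-interval memory and a clean 24 h circadian period; the ICI
distribution splits at τ₀ ≈ 930 s into a power-law burst regime (µ ≈ 2)
and Weibull gaps; choices are rank-biased (58 % to the favorite) and more
persistent than any frequency-matched shuffle (p = 0.002); and the full
dual-control model beats its nested goal-only and habit-only variants by
BIC — both control systems are needed to explain the sequence.

A command-line interface wraps the same pipeline:

```bash
foragedyn simulate --out sim.csv --truth truth.json --days 14 --seed 1
foragedyn analyze  --log sim.csv --out results/ --seed 0
foragedyn fit-timing --log sim.csv --nsim 10 --seed 0
foragedyn fit-choice --log sim.csv --restarts 20 --seed 0
```

## Layout

- `foragedyn.event_model` — choice-log container, CSV I/O, light/dark labeling, pipeline driver
- `foragedyn.temporal_stats` — ICIs, B, M, windowed choice entropy, autocorrelogram period
- `foragedyn.tail_fitting` — power-law/Weibull MLE, τ₀ detection, bimodal piecewise survival, bootstrap GOF
- `foragedyn.dual_state` — dual-state simulator, burst segmentation, least-area estimation
- `foragedyn.run_analysis` — runs, run survival/hazard, ranks, log-rank fit, shuffle tests
- `foragedyn.dual_control` — dual-control model, NLL fitting, BIC/LRT/pseudo-r² comparison
- `foragedyn.synthetic_data` — composed generative datasets and analytic fixtures
- `docs/methods.md` — modelling assumptions, parameter meanings, numerical choices, limitations
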