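import numpy as np
import pytest

from foragedyn.dual_control import (
    DualControlParams,
    ModelFit,
    VARIANTS,
    choice_probabilities,
    compare_models,
    fit_choice_model,
    goal_step,
    habit_trajectory,
    lrt,
    reward_values,
    sequence_nll,
    simulate_choices,
)


def reference_nll(options, params, R, n_options=4):
    """Independent pure-python re-implementation of the forward pass."""
    import math

    use_goal, use_decay, use_habit = VARIANTS[params.variant]
    bG = params.beta_G if use_goal else 0.0
    bH = params.beta_H if use_habit else 0.0
    au = params.alpha_u if use_decay else 0.0
    decay = math.exp(-1.0 / params.kappa)
    Q = [0.0] * n_options
    H = [0.0] * n_options
    nll = 0.0
    for c in options:
        z = [bG * Q[i] + bH * H[i] for i in range(n_options)]
        m = max(z)
        denom = sum(math.exp(v - m) for v in z)
        nll -= z[c] - m - math.log(denom)
        if use_goal:
            for i in range(n_options):
                if i == c:
                    Q[i] += params.alpha_c * (R[c] - Q[i])
                else:
                    Q[i] += au * (0.0 - Q[i])
        if use_habit:
            H = [decay * h for h in H]
            H[c] += decay
    return nll


class TestHabitTrajectory:
    def test_single_choice_one_step(self):
        H = habit_trajectory(np.array([0, 1]), kappa=5.0, n_options=4)
        assert H[1, 0] == pytest.approx(np.exp(-1.0 / 5.0))
        assert H[0].sum() == 0.0

    def test_geometric_series_limit(self):
        kappa = 7.0
        H = habit_trajectory(np.zeros(2000, dtype=int), kappa=kappa, n_options=4)
        d = np.exp(-1.0 / kappa)
        assert H[-1, 0] == pytest.approx(d / (1.0 - d), rel=1e-6)

    def test_recursion_matches_direct_kernel_sum(self, rng):
        options = rng.integers(0, 4, 500)
        kappa = 12.0
        H = habit_trajectory(options, kappa=kappa, n_options=4)
        # direct evaluation of the kernel sum at a handful of trials
        for t in [1, 7, 100, 499]:
            for i in range(4):
                direct = sum(
                    np.exp(-tau / kappa)
                    for tau in range(1, t + 1)
                    if options[t - tau] == i
                )
                assert H[t, i] == pytest.approx(direct, abs=1e-12)

    def test_bounded_by_saturation_value(self, rng):
        kappa = 9.0
        H = habit_trajectory(rng.integers(0, 4, 1000), kappa=kappa, n_options=4)
        d = np.exp(-1.0 / kappa)
        assert np.all(H <= d / (1.0 - d) + 1e-9)
        assert np.all(H >= 0.0)


class TestRewardValues:
    def test_proportional_at_unit_sensitivity(self):
        R = reward_values(np.array([0.5, 0.25, 0.15, 0.10]), a=1.0)
        np.testing.assert_allclose(R, [1.0, 0.5, 0.3, 0.2])

    def test_square_root_at_a2(self):
        R = reward_values(np.array([0.5, 0.25, 0.15, 0.10]), a=2.0)
        np.testing.assert_allclose(R, [1.0, 0.7071, 0.5477, 0.4472], atol=1e-4)

    def test_equal_rates_equal_values(self):
        R = reward_values(np.full(4, 0.25), a=1.7)
        np.testing.assert_allclose(R, np.ones(4))

    def test_invalid_sensitivity(self):
        with pytest.raises(ValueError):
            reward_values(np.full(4, 0.25), a=0.0)


class TestGoalStep:
    def test_chosen_update(self):
        Q = goal_step(np.zeros(4), choice=0, R_c=1.0, alpha_c=0.5, alpha_u=0.25)
        assert Q[0] == 0.5

    def test_unchosen_decay(self):
        Q = goal_step(np.array([0.1, 0.8, 0.0, 0.0]), 0, 1.0, 0.5, 0.25)
        assert Q[1] == pytest.approx(0.6)

    def test_repeated_choice_converges_to_reward(self):
        Q = np.zeros(4)
        for _ in range(200):
            Q = goal_step(Q, 2, 0.7, 0.3, 0.1)
        assert Q[2] == pytest.approx(0.7, rel=1e-6)


class TestChoiceProbabilities:
    def test_uniform_when_flat(self):
        np.testing.assert_allclose(
            choice_probabilities(np.ones(4), np.ones(4), 2.0, 3.0), np.full(4, 0.25)
        )

    def test_zero_temperatures_uniform(self, rng):
        p = choice_probabilities(rng.random(4), rng.random(4), 0.0, 0.0)
        np.testing.assert_allclose(p, np.full(4, 0.25))

    def test_softmax_arithmetic(self):
        p = choice_probabilities(np.array([1.0, 0, 0, 0]), np.zeros(4), np.log(3.0), 0.0)
        np.testing.assert_allclose(p, [0.5, 1 / 6, 1 / 6, 1 / 6])

    def test_sums_to_one_even_with_huge_values(self, rng):
        p = choice_probabilities(1e4 * rng.random(4), 1e3 * rng.random(4), 50.0, 50.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestSequenceNLL:
    def test_uniform_model_is_n_ln4(self, rng):
        seq = rng.integers(0, 4, 250)
        params = DualControlParams(variant="habit", beta_H=0.0)
        assert sequence_nll(seq, params) == pytest.approx(250 * np.log(4.0))

    def test_matches_reference_oracle(self, rng):
        R = np.array([1.0, 0.5, 0.3, 0.2])
        for variant in VARIANTS:
            params = DualControlParams(
                alpha_c=0.4, alpha_u=0.2, a=1.1, kappa=8.0,
                beta_G=2.0, beta_H=0.3, variant=variant,
            )
            seq = rng.integers(0, 4, 200)
            assert sequence_nll(seq, params, R=R) == pytest.approx(
                reference_nll(seq, params, R), abs=1e-10
            )

    def test_deterministic_repeat_limit(self):
        # large habit temperature on a constant sequence: P(choice) -> 1
        seq = np.zeros(100, dtype=int)
        params = DualControlParams(variant="habit", beta_H=50.0, kappa=50.0)
        nll = sequence_nll(seq, params)
        assert nll < np.log(4.0) + 1.0  # only the first trial is uncertain


class TestUnchosenDecayEffect:
    def test_decay_increases_next_prediction_error(self):
        """With alpha_u > 0 an unchosen option's value decays, so re-choosing
        it later yields a strictly larger reward prediction error."""
        R = np.array([1.0, 0.8, 0.3, 0.2])
        # option 1 holds value 0.5, then goes unchosen while 0 is chosen
        Q_no_decay = np.array([0.0, 0.5, 0.0, 0.0])
        Q_decay = Q_no_decay.copy()
        for _ in range(3):
            Q_no_decay = goal_step(Q_no_decay, 0, R[0], 0.5, 0.0)
            Q_decay = goal_step(Q_decay, 0, R[0], 0.5, 0.3)
        assert np.all(np.diff([0.5, Q_decay[1]]) < 0)  # monotone decay happened
        assert (R[1] - Q_decay[1]) > (R[1] - Q_no_decay[1])


class TestFitAndCompare:
    def test_bic_formula(self):
        fit = ModelFit(params=DualControlParams(), nll=100.0, k=6, n=1000)
        assert fit.bic == pytest.approx(200.0 + 6 * np.log(1000.0))
        assert fit.bic == pytest.approx(241.45, abs=0.01)

    def test_pseudo_r2_formula(self):
        fit = ModelFit(params=DualControlParams(), nll=700.0, k=6, n=1000)
        expected = (1000 * np.log(0.25) + 700.0) / (1000 * np.log(0.25))
        assert fit.pseudo_r2 == pytest.approx(expected)
        assert fit.pseudo_r2 == pytest.approx(0.495, abs=0.001)

    def test_iid_data_pseudo_r2_near_zero(self, rng):
        seq = rng.integers(0, 4, 2000)
        fit = fit_choice_model(seq, variant="habit", restarts=5, seed=0)
        assert abs(fit.pseudo_r2) < 0.01

    def test_fitted_nll_beats_generating_params(self):
        params = DualControlParams()
        R = reward_values(np.array([0.5, 0.25, 0.15, 0.10]), params.a)
        seq = simulate_choices(params, R, 2000, seed=4)
        fit = fit_choice_model(seq, variant="dual", restarts=5, seed=0)
        assert fit.nll <= sequence_nll(seq, params) + 1e-6

    def test_non_nested_lrt_refused(self):
        a = ModelFit(params=DualControlParams(variant="goal_c"), nll=10.0, k=3, n=100)
        b = ModelFit(params=DualControlParams(variant="habit"), nll=12.0, k=2, n=100)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_comparison_table(self, persistent_sequence):
        fits = [
            fit_choice_model(persistent_sequence, variant=v, restarts=5, seed=i)
            for i, v in enumerate(["dual", "habit", "goal_c"])
        ]
        table = compare_models(fits)
        assert set(table["variant"]) == {"dual", "habit", "goal_c"}
        assert table["winner"].sum() == 1
        best = table.loc[table["winner"], "bic"].iloc[0]
        assert (table["bic"] >= best - 1e-9).all()
        # habit and goal_c rows carry an LRT against dual
        sub = table.set_index("variant")
        assert sub.loc["habit", "lrt_vs"] == "dual"
        assert sub.loc["habit", "lrt_stat"] >= 0 or sub.loc["habit", "lrt_p"] >= 0


class TestSimulateChoices:
    def test_zero_temperatures_uniform_frequencies(self):
        params = DualControlParams(beta_G=0.0, beta_H=0.0)
        seq = simulate_choices(params, np.ones(4), 10_000, seed=5)
        counts = np.bincount(seq, minlength=4)
        chi2 = ((counts - 2500.0) ** 2 / 2500.0).sum()
        assert chi2 < 16.27  # chi-square(3) at alpha=0.001

    def test_habit_dominant_produces_long_runs(self):
        from foragedyn.run_analysis import extract_runs

        params = DualControlParams(variant="habit", beta_H=0.5, kappa=20.0)
        seq = simulate_choices(params, np.ones(4), 3000, seed=6)
        runs = extract_runs(seq)
        assert runs.lengths.max() > 50

    def test_hazard_decreases_for_habit_but_not_iid(self, rng):
        from foragedyn.run_analysis import extract_runs, run_distribution

        params = DualControlParams(variant="habit", beta_H=0.15, kappa=15.0)
        seq = simulate_choices(params, np.ones(4), 20_000, seed=7)
        dist = run_distribution(extract_runs(seq))
        early = np.nanmean(dist.hazard[:2])
        late = np.nanmean(dist.hazard[4:8])
        assert late < early  # preferential attachment: runs get stickier
        iid = run_distribution(extract_runs(rng.integers(0, 4, 20_000)))
        assert abs(np.nanmean(iid.hazard[:2]) - np.nanmean(iid.hazard[2:4])) < 0.05

    def test_reproducible(self):
        params = DualControlParams()
        R = np.ones(4)
        a = simulate_choices(params, R, 500, seed=8)
        b = simulate_choices(params, R, 500, seed=8)
        np.testing.assert_array_equal(a, b)
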