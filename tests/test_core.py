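"""Game structure, utility models, predictions, and behavior generation."""

import numpy as np
import pytest

from hmtg.core import (
    BehaviorDataset,
    ComponentParams,
    MSParams,
    TaskSchedule,
    Trial,
    build_schedule,
    params_from_json,
    params_to_json,
    predict_combos,
    predict_return,
    predict_schedule,
    prototype_returns,
    read_behavior_csv,
    read_schedule_csv,
    simulate_behavior,
    utility,
    write_behavior_csv,
    write_schedule_csv,
)


def oracle_predict(model, theta, phi, investment, multiplier):
    """Naive double-loop argmax, written directly from the model definitions."""
    pot = investment * multiplier
    best_s2, best_u = 0, -np.inf
    for s2 in range(pot + 1):
        payoff = pot - s2
        guilt = ((2 * investment - s2) / (4 * investment)) ** 2
        inequity = (payoff / (10 - investment + pot) - 0.5) ** 2
        if model == "MS":
            u = theta * payoff / pot - (1 - theta) * min(guilt + phi, inequity - phi)
        elif model == "GR":
            u = payoff
        elif model == "GA":
            u = payoff - theta * guilt
        else:
            u = payoff - theta * inequity
        if u > best_u:
            best_s2, best_u = s2, u
    return best_s2


class TestSchedule:
    def test_standard_invariants(self):
        s = build_schedule(0)
        assert len(s) == 80
        assert int((s.investments > 0).sum()) == 76
        mult = s.multipliers
        assert {m: int((mult == m).sum()) for m in (2, 4, 6)} == {2: 20, 4: 40, 6: 20}
        # 5% zero-investment trials per condition
        for m, n_zero in ((2, 1), (4, 2), (6, 1)):
            assert int(((mult == m) & (s.investments == 0)).sum()) == n_zero
        # nonzero investments near-identically distributed across conditions
        for m in (2, 4, 6):
            inv = s.investments[(mult == m) & (s.investments > 0)]
            counts = np.bincount(inv, minlength=11)[1:]
            assert counts.max() - counts.min() <= 1

    def test_deterministic_per_seed(self):
        a, b = build_schedule(3), build_schedule(3)
        assert a.trials == b.trials
        assert build_schedule(4).trials != a.trials


class TestUtility:
    def test_ms_worked_example(self):
        t = utility("MS", MSParams(0.5, 0.0), Trial(10, 4), 0)
        assert t.payoff == 1.0
        assert t.guilt == 0.25
        assert t.inequity == 0.25
        assert t.utility == pytest.approx(0.375)

    def test_guilt_vanishes_at_expected_return(self):
        t = utility("MS", MSParams(0.0, 0.0), Trial(5, 4), 10)
        assert t.guilt == 0.0
        assert t.utility == pytest.approx(0.0)

    def test_greed_utility_is_raw_payoff(self):
        assert utility("GR", None, Trial(10, 6), 0).utility == 60.0

    def test_zero_investment_rejected(self):
        with pytest.raises(ValueError):
            utility("MS", MSParams(0.1, 0.0), Trial(0, 4), 0)

    def test_out_of_range_return_rejected(self):
        with pytest.raises(ValueError):
            utility("MS", MSParams(0.1, 0.0), Trial(5, 2), 11)

    def test_terms_nonnegative_and_payoff_normalized(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            trial = Trial(int(rng.integers(1, 11)), int(rng.choice([2, 4, 6])))
            s2 = int(rng.integers(0, trial.pot + 1))
            t = utility("MS", MSParams(rng.uniform(0, 0.5), rng.uniform(-0.1, 0.1)), trial, s2)
            assert t.guilt >= 0 and t.inequity >= 0
            assert 0.0 <= t.payoff <= 1.0


class TestPredict:
    def test_greed_always_returns_zero(self):
        for i in range(1, 11):
            for m in (2, 4, 6):
                assert predict_return("GR", None, Trial(i, m)) == 0

    def test_opportunist_pattern(self):
        # small greed, no bias: follow the cheaper moral rule per condition
        p = MSParams(0.02, 0.0)
        assert predict_return("MS", p, Trial(5, 2)) == 2
        assert predict_return("MS", p, Trial(5, 4)) == 7
        assert predict_return("MS", p, Trial(5, 6)) == 10

    def test_component_limits(self):
        # the guilt term dominates only once theta exceeds 16*I^2
        assert predict_return("GA", ComponentParams(900.0), Trial(7, 4)) == 14
        assert predict_return("IA", ComponentParams(1000.0), Trial(10, 2)) == 10

    def test_zero_investment_convention(self):
        assert predict_return("MS", MSParams(0.1, 0.0), Trial(0, 4)) == 0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            model = rng.choice(["MS", "GR", "GA", "IA"])
            i = int(rng.integers(1, 11))
            m = int(rng.choice([2, 4, 6]))
            if model == "MS":
                theta = rng.uniform(0, 0.5)
                phi = rng.uniform(-0.1, 0.1)
                params = MSParams(theta, phi)
            else:
                theta = rng.uniform(0, 1000)
                phi = 0.0
                params = ComponentParams(theta) if model != "GR" else None
            got = predict_return(model, params, Trial(i, m))
            assert got == oracle_predict(model, theta, phi, i, m)

    def test_prediction_in_range_exhaustive(self):
        thetas = np.linspace(0, 0.5, 11)
        phis = np.linspace(-0.1, 0.1, 9)
        tt, pp = np.meshgrid(thetas, phis)
        inv = np.repeat(np.arange(1, 11), 3)
        mult = np.tile([2, 4, 6], 10)
        preds = predict_combos("MS", tt.ravel(), pp.ravel(), inv, mult)
        assert np.all(preds >= 0)
        assert np.all(preds <= inv * mult)


class TestPrototypes:
    @pytest.mark.parametrize(
        "strategy,trial,expected",
        [
            ("GA", Trial(5, 2), 10),
            ("IA", Trial(10, 4), 20),
            ("MO", Trial(5, 6), 10),
            ("MO", Trial(5, 2), 2),
            ("GR", Trial(8, 6), 0),
            ("IA", Trial(1, 2), 0),  # equal split infeasible; clipped at 0
        ],
    )
    def test_examples(self, strategy, trial, expected):
        assert prototype_returns(strategy, trial) == expected

    def test_mo_is_pointwise_min_of_ga_and_ia(self):
        for i in range(1, 11):
            for m in (2, 4, 6):
                t = Trial(i, m)
                assert prototype_returns("MO", t) == min(
                    prototype_returns("GA", t), prototype_returns("IA", t)
                )

    def test_ms_limit_reproduces_ga_prototype(self):
        # phi = -0.2 (outside fitted bounds, test-only) forces the guilt branch
        inv = np.repeat(np.arange(1, 11), 3)
        mult = np.tile([2, 4, 6], 10)
        preds = predict_combos("MS", np.array([0.0]), np.array([-0.2]), inv, mult)[0]
        protos = np.array([prototype_returns("GA", Trial(int(i), int(m))) for i, m in zip(inv, mult)])
        assert np.array_equal(preds, protos)

    def test_ms_limit_reproduces_ia_prototype(self):
        preds_inv = np.repeat(np.arange(1, 11), 3)
        mult = np.tile([2, 4, 6], 10)
        preds = predict_combos("MS", np.array([0.0]), np.array([0.2]), preds_inv, mult)[0]
        protos = np.array(
            [prototype_returns("IA", Trial(int(i), int(m))) for i, m in zip(preds_inv, mult)]
        )
        assert np.max(np.abs(preds - protos)) <= 1

    def test_pure_greed_limit(self):
        # theta = 1 (test-only, outside fitted bounds) removes the social term
        inv = np.repeat(np.arange(1, 11), 3)
        mult = np.tile([2, 4, 6], 10)
        preds = predict_combos("MS", np.array([1.0]), np.array([0.0]), inv, mult)[0]
        assert np.all(preds == 0)
        # within bounds, the upper-theta zone is near-greedy, not exactly zero
        preds_bound = predict_combos("MS", np.array([0.5]), np.array([0.0]), inv, mult)[0]
        assert np.mean(preds_bound == 0) > 0.9


class TestSimulateBehavior:
    def test_noiseless_equals_predictions(self, schedule):
        p = MSParams(0.1, 0.02)
        d = simulate_behavior("MS", p, schedule)
        assert np.array_equal(d.returned, predict_schedule("MS", p, schedule))

    def test_same_seed_identical(self, schedule):
        a = simulate_behavior("MS", MSParams(0.1, 0.0), schedule, noise_sd=2.0, seed=5)
        b = simulate_behavior("MS", MSParams(0.1, 0.0), schedule, noise_sd=2.0, seed=5)
        assert np.array_equal(a.returned, b.returned)

    def test_negative_noise_rejected(self, schedule):
        with pytest.raises(ValueError):
            simulate_behavior("MS", MSParams(0.1, 0.0), schedule, noise_sd=-1.0)

    def test_noise_scale_monte_carlo(self, schedule):
        # deviation variance tracks sigma^2 = 5.29, shrunk by clipping at the
        # feasible-range boundaries (measured ~4.2 for these parameters)
        p = MSParams(0.1, 0.0)
        pred = predict_schedule("MS", p, schedule)
        m = schedule.modeled
        devs = [
            np.mean(
                (simulate_behavior("MS", p, schedule, noise_sd=2.3, seed=s).returned[m] - pred[m])
                ** 2
            )
            for s in range(60)
        ]
        assert 3.5 < np.mean(devs) < 5.6

    def test_zero_investment_trials_return_zero(self, schedule):
        d = simulate_behavior("MS", MSParams(0.0, -0.1), schedule, noise_sd=5.0, seed=0)
        assert np.all(d.returned[~schedule.modeled] == 0)


class TestIO:
    def test_behavior_roundtrip(self, schedule, tmp_path):
        ds = [
            simulate_behavior("MS", MSParams(0.1, 0.0), schedule, 1.5, seed=i, participant_id=f"p{i}")
            for i in range(3)
        ]
        path = tmp_path / "behavior.csv"
        write_behavior_csv(ds, path)
        back = read_behavior_csv(path)
        assert [d.participant_id for d in back] == ["p0", "p1", "p2"]
        for a, b in zip(ds, back):
            assert np.array_equal(a.returned, b.returned)
            assert a.schedule.trials == b.schedule.trials

    def test_schedule_roundtrip(self, schedule, tmp_path):
        path = tmp_path / "schedule.csv"
        write_schedule_csv(schedule, path)
        assert read_schedule_csv(path).trials == schedule.trials

    def test_params_json_roundtrip(self):
        model, params = params_from_json(params_to_json("MS", MSParams(0.3, -0.05)))
        assert model == "MS" and params == MSParams(0.3, -0.05)
        model, params = params_from_json(params_to_json("GA", ComponentParams(12.5)))
        assert model == "GA" and params.theta == 12.5

    def test_invalid_behavior_rejected(self, schedule):
        bad = np.zeros(len(schedule), dtype=int)
        bad[0] = schedule.pots[0] + 1 if schedule.pots[0] else 1
        with pytest.raises(ValueError):
            BehaviorDataset("x", schedule, bad)
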