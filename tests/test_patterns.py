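"""Cluster strength, sign-flip inference, strategy maps, and the MO shift."""

import numpy as np
import pytest
from scipy.stats import binomtest, kstest

from hmtg.cohort import NeuralDataset, ParcelSpec, generate_neural
from hmtg.patterns import (
    build_strategy_map,
    cluster_strength,
    cluster_strength_scores,
    cross_condition_scores,
    ga_ia_difference_map,
    group_sign_test,
    mo_shift_analysis,
    strategy_map_tests,
)


def _dataset_from_patterns(per_condition: dict, ids=None):
    """Build a one-parcel NeuralDataset from {condition: (n, v) array}."""
    n = len(next(iter(per_condition.values())))
    arr = np.stack([per_condition[c] for c in ("x2", "x4", "x6")], axis=1)
    return NeuralDataset(
        participant_ids=ids or [f"p{i}" for i in range(n)],
        betas={"a": arr},
        parcel_specs={},
    )


class TestClusterStrengthScore:
    def test_arithmetic(self):
        assert cluster_strength(0.2, 0.4) == pytest.approx(0.5)
        assert cluster_strength(0.3, 0.3) == 0.0
        assert cluster_strength(0.0, 0.5) == 1.0
        assert cluster_strength(0.5, 0.0) == -1.0

    def test_strictly_decreasing_in_within(self):
        scores = [cluster_strength(w, 0.4) for w in (0.1, 0.2, 0.3, 0.5, 0.7)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            w, b = rng.uniform(0, 2, size=2)
            assert -1 <= cluster_strength(w, b) <= 1

    def test_perfect_grouping_scores_one(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(20)
        noise = rng.standard_normal((3, 20))
        pats = np.vstack([t, t, t, noise])
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        labels = ["GA", "GA", "GA", "IA", "IA", "IA"]
        scores = cluster_strength_scores(ds, "x4", "a", labels, "GA", exclude_groups=())
        assert all(s.score == pytest.approx(1.0) for s in scores)
        assert all(s.within_mean == pytest.approx(0.0) for s in scores)

    def test_small_group_and_empty_pool_rejected(self):
        rng = np.random.default_rng(2)
        pats = rng.standard_normal((4, 10))
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        with pytest.raises(ValueError):
            cluster_strength_scores(ds, "x4", "a", ["GA", "IA", "IA", "IA"], "GA")
        with pytest.raises(ValueError):
            cluster_strength_scores(ds, "x4", "a", ["GA", "GA", "GR", "GR"], "GA")


class TestCrossConditionScores:
    def test_condition_stable_templates_score_one(self):
        rng = np.random.default_rng(3)
        t = rng.standard_normal(20)
        noise = rng.standard_normal((2, 20))
        pats = np.vstack([t, t, noise])
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        labels = ["GA", "GA", "IA", "IA"]
        scores = cross_condition_scores(ds, "a", labels, "GA", to_condition="x2")
        assert all(s.score == pytest.approx(1.0) for s in scores)

    def test_random_labels_on_noise_average_zero(self):
        rng = np.random.default_rng(4)
        means = []
        for rep in range(40):
            pats = {c: rng.standard_normal((10, 30)) for c in ("x2", "x4", "x6")}
            ds = _dataset_from_patterns(pats)
            labels = list(rng.permutation(["GA"] * 5 + ["IA"] * 5))
            s = cross_condition_scores(ds, "a", labels, "GA", to_condition="x2")
            means.append(np.mean([x.score for x in s]))
        assert abs(np.mean(means)) < 0.05


class TestGroupSignTest:
    def test_all_zero_scores_not_significant(self):
        assert group_sign_test([0.0] * 6) == pytest.approx(1.0)

    def test_exhaustive_enumeration(self):
        # 5 strongly positive scores: only the identity flip ties the mean
        assert group_sign_test([0.5, 0.6, 0.4, 0.55, 0.45]) == pytest.approx(1 / 32)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            group_sign_test([0.5])

    def test_p_uniform_under_null(self):
        # scores from pure-noise parcels with arbitrary labels; exhaustive
        # flips (group of 8 -> lattice of 1/256) should give ~uniform p
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(200):
            pats = {c: rng.standard_normal((12, 30)) for c in ("x2", "x4", "x6")}
            ds = _dataset_from_patterns(pats)
            labels = ["GA"] * 8 + ["IA"] * 4
            scores = cluster_strength_scores(ds, "x4", "a", labels, "GA")
            pvals.append(group_sign_test(scores, n_perm=500))
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_planted_template_detected_and_nulls_calibrated(self, cohort_default):
        specs = [ParcelSpec("coded", "group_template", coded_groups=("GA",))]
        neu = generate_neural(cohort_default, specs, noise_sd_voxel=1.0, seed=6)
        scores = cluster_strength_scores(neu, "x4", "coded", cohort_default.labels, "GA")
        assert group_sign_test(scores, seed=0) < 0.05


class TestStrategyMap:
    def test_conjunction_logic(self):
        within = {("GA", "p1"): 0.01, ("GA", "p2"): 0.01, ("IA", "p1"): 0.2}
        to_x2 = {("GA", "p1"): 0.04, ("GA", "p2"): 0.2, ("IA", "p1"): 0.01}
        to_x6 = {("GA", "p1"): 0.04, ("GA", "p2"): 0.01, ("IA", "p1"): 0.01}
        smap = build_strategy_map(within, to_x2, to_x6, alpha=0.05, strategies=("GA", "IA"))
        assert smap["GA"] == {"p1"}  # p2 fails the x2 generalization
        assert smap["IA"] == set()  # fails the within test
        assert smap.exclusive("GA", "IA") == {"p1"}

    def test_conjunction_false_positive_rate_bounded(self):
        # under pure-noise parcels the conjunction rate should be ~alpha^3
        rng = np.random.default_rng(7)
        alpha = 0.3
        hits = 0
        n_parcels = 150
        for rep in range(n_parcels):
            pats = {c: rng.standard_normal((12, 30)) for c in ("x2", "x4", "x6")}
            ds = _dataset_from_patterns(pats)
            labels = ["GA"] * 6 + ["IA"] * 6
            p_w = group_sign_test(cluster_strength_scores(ds, "x4", "a", labels, "GA"), n_perm=200)
            p_2 = group_sign_test(
                cross_condition_scores(ds, "a", labels, "GA", to_condition="x2"), n_perm=200
            )
            p_6 = group_sign_test(
                cross_condition_scores(ds, "a", labels, "GA", to_condition="x6"), n_perm=200
            )
            hits += (p_w < alpha) and (p_2 < alpha) and (p_6 < alpha)
        # one-sided binomial check against alpha^3 (= 0.027)
        assert binomtest(hits, n_parcels, alpha**3, alternative="greater").pvalue > 1e-3


class TestDifferenceMap:
    def test_identical_groups_give_zero_map(self):
        rng = np.random.default_rng(8)
        t = rng.standard_normal(20)
        pats = np.vstack([t, t, t, t])
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        d = ga_ia_difference_map(ds, ["GA", "GA", "IA", "IA"], "x2", "a")
        assert np.allclose(d, 0)

    def test_label_swap_negates_map(self):
        rng = np.random.default_rng(9)
        pats = rng.standard_normal((4, 20))
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        a = ga_ia_difference_map(ds, ["GA", "GA", "IA", "IA"], "x2", "a")
        b = ga_ia_difference_map(ds, ["IA", "IA", "GA", "GA"], "x2", "a")
        assert np.allclose(a, -b)

    def test_switching_parcel_map_recovers_template_contrast(self, cohort_default):
        specs = [ParcelSpec("sw", "switching")]
        neu = generate_neural(cohort_default, specs, noise_sd_voxel=0.0, seed=10)
        labels = cohort_default.labels
        d = ga_ia_difference_map(neu, labels, "x6", "sw")
        ga_idx = labels.index("GA")
        ia_idx = labels.index("IA")
        t_ga = neu.betas["sw"][ga_idx, 2]
        t_ia = neu.betas["sw"][ia_idx, 2]

        def z(v):
            return (v - v.mean()) / v.std()

        assert np.allclose(d, z(t_ga) - z(t_ia), atol=1e-10)

    def test_missing_group_rejected(self):
        rng = np.random.default_rng(11)
        pats = rng.standard_normal((3, 10))
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        with pytest.raises(ValueError):
            ga_ia_difference_map(ds, ["GA", "GA", "MO"], "x2", "a")


class TestMOShift:
    def test_noiseless_switching_gives_perfect_classification(self, cohort_default):
        specs = [ParcelSpec(f"sw{i}", "switching") for i in range(3)]
        neu = generate_neural(cohort_default, specs, noise_sd_voxel=0.0, seed=12)
        res = mo_shift_analysis(neu, cohort_default.labels)
        assert res.accuracy == 1.0
        assert res.delta_r > 0
        by_subj = res.similarities.pivot_table(
            index="participant_id", columns="condition", values="similarity"
        )
        assert np.all(by_subj["x6"] > 0)
        assert np.all(by_subj["x2"] < 0)

    def test_noise_only_mo_patterns_classify_at_chance(self, cohort_default):
        # planted templates for GA/IA but MO patterns are pure noise
        specs = [
            ParcelSpec(f"t{i}", "group_template", coded_groups=("GA", "IA"))
            for i in range(4)
        ]
        neu = generate_neural(cohort_default, specs, noise_sd_voxel=1.0, seed=13)
        res = mo_shift_analysis(neu, cohort_default.labels)
        assert 0.15 <= res.accuracy <= 0.85
        assert abs(res.delta_r) < 0.1

    def test_accuracy_monotone_in_snr(self, cohort_default):
        accs = []
        for amp in (0.3, 1.0, 4.0):
            specs = [ParcelSpec(f"sw{i}", "switching", amplitude=amp) for i in range(3)]
            neu = generate_neural(cohort_default, specs, noise_sd_voxel=1.0, seed=14)
            accs.append(mo_shift_analysis(neu, cohort_default.labels).accuracy)
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] > 0.9

    def test_needs_two_mo_participants(self):
        rng = np.random.default_rng(15)
        pats = rng.standard_normal((3, 10))
        ds = _dataset_from_patterns({c: pats for c in ("x2", "x4", "x6")})
        with pytest.raises(ValueError):
            mo_shift_analysis(ds, ["GA", "IA", "MO"])


class TestEndToEndRecovery:
    def test_strategy_maps_recover_planted_structure_at_high_snr(self, cohort_default, neural_high_snr):
        smap, _, skipped = strategy_map_tests(
            neural_high_snr, cohort_default.labels, n_perm=2000, seed=16
        )
        assert not skipped
        parcel_kind = {p: s.kind for p, s in neural_high_snr.parcel_specs.items()}
        coded = {p: s.coded_groups for p, s in neural_high_snr.parcel_specs.items()}
        for strategy in ("GA", "IA", "MO"):
            # no pure-noise parcel enters any map
            assert not any(parcel_kind[p] == "null" for p in smap[strategy])
            # every template parcel coded for this strategy is recovered
            expected = {
                p for p, k in parcel_kind.items()
                if k == "group_template" and strategy in coded[p]
            }
            assert expected <= smap[strategy]
        # condition-stable templates: switching parcels generalize for GA/IA
        switching = {p for p, k in parcel_kind.items() if k == "switching"}
        assert switching <= smap["GA"] and switching <= smap["IA"]
        # MO's x4 mixture matches neither group across conditions strongly
        # enough to cluster exclusively; switching parcels stay out of MO's map
        assert not (switching & smap["MO"])

    def test_detection_degrades_with_noise(self, cohort_default):
        hits = []
        for noise in (0.2, 2.0, 8.0):
            specs = [
                ParcelSpec(f"t{i}", "group_template", coded_groups=("GA", "IA", "MO"))
                for i in range(4)
            ]
            neu = generate_neural(cohort_default, specs, noise_sd_voxel=noise, seed=17)
            smap, _, _ = strategy_map_tests(neu, cohort_default.labels, n_perm=400, seed=18)
            hits.append(sum(len(smap[s]) for s in ("GA", "IA", "MO")))
        assert hits[0] >= hits[1] >= hits[2]
        assert hits[0] == 12  # 4 parcels x 3 strategies at near-zero noise
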