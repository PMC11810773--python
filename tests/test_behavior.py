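"""Lick analyses, startle scoring, loom metrics, and trend statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest, mannwhitneyu

from goggleskit import synth
from goggleskit.behavior import (
    CHANCE_ZONE_FRACTION,
    HABITABLE_LENGTH_M,
    classify_licks,
    cuzick_trend_test,
    fit_startle_decay,
    lick_position_map,
    loom_response_metrics,
    mann_whitney_u,
    probe_trial_split,
    startle_classify,
    zone_preference,
)


class TestClassifyLicks:
    def test_burst_rule_example(self):
        labels = classify_licks([11.0, 11.5, 12.0, 14.0], [10.0])
        assert list(labels) == ["post_reward"] * 3 + ["exploratory"]

    def test_late_lick_is_exploratory(self):
        labels = classify_licks([14.5], [10.0])
        assert list(labels) == ["exploratory"]

    def test_no_rewards_all_exploratory(self):
        labels = classify_licks([1.0, 2.0, 3.0], [])
        assert set(labels) == {"exploratory"}

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        licks = np.sort(rng.uniform(0, 100, 200))
        rewards = np.sort(rng.uniform(0, 100, 10))
        labels = classify_licks(licks, rewards)
        assert len(labels) == len(licks)
        assert set(labels) <= {"post_reward", "exploratory"}


class TestLickMap:
    def test_habitable_bin_count_and_length(self):
        t = np.arange(0, 100, 0.05)
        pos = np.mod(0.15 * t, 1.5)
        m = lick_position_map([], t, pos)
        assert m["habitable"].sum() == 28
        assert HABITABLE_LENGTH_M == pytest.approx(1.42)

    def test_uniform_licking_equal_rates(self):
        t = np.arange(0, 150, 0.01)
        pos = np.mod(0.1 * t, 1.5)
        licks = np.arange(0.5, 149.5, 0.5)
        m = lick_position_map(licks, t, pos)
        rates = m["lick_rate_hz"][m["habitable"]]
        assert np.nanstd(rates) / np.nanmean(rates) < 0.2


class TestZonePreference:
    def _map(self, counts):
        habitable = np.ones(30, dtype=bool)
        habitable[0] = habitable[-1] = False
        return {"lick_counts": np.asarray(counts), "habitable": habitable}

    def test_chance_level(self):
        assert CHANCE_ZONE_FRACTION == pytest.approx(0.3571, abs=2e-4)

    def test_all_in_zone(self):
        counts = np.zeros(30, dtype=int)
        counts[7] = 20  # inside the 0.25-0.75 m zone
        assert zone_preference(self._map(counts), 0.5)["fraction"] == 1.0

    def test_uniform_equals_chance(self):
        counts = np.zeros(30, dtype=int)
        counts[1:29] = 5
        res = zone_preference(self._map(counts), 0.5)
        assert res["fraction"] == pytest.approx(res["chance"])

    def test_zone_clipped_raises(self):
        with pytest.raises(ValueError):
            zone_preference(self._map(np.ones(30)), 0.1)


class TestProbeSplit:
    def test_partition(self):
        bounds = [(0, 10), (10, 20), (20, 30)]
        rewarded, probe = probe_trial_split(bounds, [5.0, 25.0])
        assert rewarded == [(0, 10), (20, 30)]
        assert probe == [(10, 20)]

    def test_empty(self):
        assert probe_trial_split([], []) == ([], [])


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=5), rng.normal(size=6)
        assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])

    def test_exact_mode_matches_enumeration_oracle(self):
        # all (n_x, n_y) with n_x + n_y <= 8, against brute force
        rng = np.random.default_rng(2)
        for nx in range(1, 7):
            for ny in range(1, 9 - nx):
                x = rng.integers(0, 5, nx).astype(float)
                y = rng.integers(0, 5, ny).astype(float)
                u_obs, p = mann_whitney_u(x, y)
                pooled = np.concatenate([x, y])
                mu = nx * ny / 2

                def ustat(a, b):
                    return sum(
                        np.sum(ai > b) + 0.5 * np.sum(ai == b) for ai in a
                    )

                devs = [
                    abs(ustat(pooled[list(c)], np.delete(pooled, list(c))) - mu)
                    for c in itertools.combinations(range(nx + ny), nx)
                ]
                expected = np.mean(
                    [d >= abs(u_obs - mu) - 1e-12 for d in devs]
                )
                assert p == pytest.approx(expected)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x, y = rng.normal(size=6), rng.normal(size=7)
            _, p = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, method="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_normal_mode(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 15), rng.normal(1.0, 1, 15)
        _, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestStartle:
    def test_scoring_rule(self):
        scores = {
            "clip1": {"s1": {"startle": 3, "tense_up": 1}, "s2": {"startle": 2}},
            "clip2": {"s1": {"startle": 1}, "s2": {"tense_up": 1}},
            "clip3": {"s1": {"startle": 1}, "s2": {"startle": 2}},
        }
        res = startle_classify(scores)
        assert res["clip_scores"]["clip1"] == 2.5 and res["is_startle"]["clip1"]
        assert res["clip_scores"]["clip2"] == 1.0 and not res["is_startle"]["clip2"]
        # boundary 1.5 is classified positive
        assert res["clip_scores"]["clip3"] == 1.5 and res["is_startle"]["clip3"]

    def test_missing_scorer_excluded(self):
        res = startle_classify({"c": {"s1": {"startle": 3}}})
        assert res["excluded"] == ["c"]

    def test_decay_fit_noiseless_recovery(self):
        r = np.arange(1, 11)
        y = 0.9 * np.exp(-0.8 * (r - 1)) + 0.05
        fit = fit_startle_decay(r, y)
        assert fit.r1 == pytest.approx(0.9, abs=1e-6)
        assert fit.decay_rate == pytest.approx(0.8, abs=1e-6)
        assert fit.offset == pytest.approx(0.05, abs=1e-6)
        assert fit.predict(1) == pytest.approx(0.95)

    def test_decay_fit_constant_degenerate(self):
        fit = fit_startle_decay([1, 2, 3, 4], [0.4, 0.4, 0.4, 0.4])
        assert fit.degenerate
        assert fit.decay_rate == 0.0
        assert fit.offset == pytest.approx(0.4)

    def test_decay_limit_is_offset(self):
        fit = fit_startle_decay(np.arange(1, 8), 0.7 * np.exp(-0.5 * np.arange(7)) + 0.1)
        assert fit.predict(1e6) == pytest.approx(fit.offset)


class TestLoomMetrics:
    def test_constant_series_zero_delta(self):
        t = np.arange(0, 200, 1 / 30)
        onsets = 5.0 + np.arange(15) * 10.0
        res = loom_response_metrics(t, np.full_like(t, 3.3), onsets, kind="velocity")
        assert np.allclose(res["delta"], 0.0)
        assert all(v == pytest.approx(0.0) for v in res["set_means"].values())

    def test_step_response(self):
        t = np.arange(0, 40, 1 / 30)
        y = np.full_like(t, 10.0)
        y[(t >= 10) & (t < 13)] = 0.0  # -10 step for >= 2 s at onset
        res = loom_response_metrics(t, y, [10.0], kind="velocity")
        assert res["delta"][0] == pytest.approx(-10.0)

    def test_edge_onsets_dropped(self):
        t = np.arange(0, 30, 1 / 30)
        res = loom_response_metrics(t, np.zeros_like(t), [0.5, 15.0, 29.5], kind="pupil")
        assert len(res["delta"]) == 1

    def test_habituating_pupil_monotone_sets(self):
        t, series, onsets, _ = synth.synth_loom_session(
            habituation_rate=0.6, seed=5, noise=0.0
        )
        res = loom_response_metrics(t, series["pupil"], onsets, kind="pupil")
        means = [res["set_means"][k] for k in sorted(res["set_means"])]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestCuzick:
    def test_strong_trend_significant(self):
        groups = [[i + j * 0.1 for j in range(5)] for i in range(5)]
        z, p = cuzick_trend_test(groups, one_sided="increasing")
        assert p < 0.01

    def test_reversal_flips_direction(self):
        rng = np.random.default_rng(6)
        groups = [list(rng.normal(i * 0.5, 1, 5)) for i in range(4)]
        z1, _ = cuzick_trend_test(groups, one_sided="increasing")
        z2, _ = cuzick_trend_test(groups[::-1], one_sided="increasing")
        assert z1 == pytest.approx(-z2, abs=1e-9)

    def test_identical_values(self):
        z, p = cuzick_trend_test([[1, 1], [1, 1], [1, 1]])
        assert (z, p) == (0.0, 0.5)

    @pytest.mark.parametrize(
        "vals",
        [
            [0.3, 1.2, 0.7, 1.9, 0.1, 1.5],  # no trend (T at its null center)
            [0.3, 0.5, 0.7, 1.0, 1.2, 1.6],  # strong increasing trend
            [1.4, 0.9, 1.1, 0.8, 0.2, 0.6],  # decreasing trend
        ],
    )
    def test_matches_permutation_oracle_small_instance(self, vals):
        # exact permutation distribution of T on tiny 3-group instances
        vals = np.array(vals)
        z_obs, p_obs = cuzick_trend_test(
            [vals[:2], vals[2:4], vals[4:]], one_sided="increasing"
        )
        from itertools import permutations
        from scipy.stats import rankdata

        scores = np.repeat([1, 2, 3], 2)
        t_obs = float(np.sum(scores * rankdata(vals)))
        ts = []
        for perm in set(permutations(range(6))):
            ts.append(float(np.sum(scores * rankdata(vals)[list(perm)])))
        # mid-p handles the discreteness of T, matching the continuity-free
        # normal approximation
        exact_p = np.mean([t > t_obs for t in ts]) + 0.5 * np.mean(
            [t == t_obs for t in ts]
        )
        assert p_obs == pytest.approx(exact_p, abs=0.05)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(400):
            groups = [list(rng.normal(size=5)) for _ in range(5)]
            ps.append(cuzick_trend_test(groups, one_sided="increasing")[1])
        assert kstest(ps, "uniform").pvalue > 0.01
        # type-I error near alpha
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.03


class TestLearningPipeline:
    @staticmethod
    def _probe_zone_fraction(days, zone_center):
        fracs = []
        for d in days:
            if d["day"] < 4:
                continue
            ev = d["events"]
            licks = np.array([e[0] for e in ev if e[1] == "lick"])
            lickpos = np.array([e[2] for e in ev if e[1] == "lick"])
            probe = [
                b for b, f in zip(d["trial_bounds_s"], d["probe_flags"]) if f
            ]
            if not probe or len(licks) == 0:
                continue
            sel = np.any([(licks >= lo) & (licks < hi) for lo, hi in probe], axis=0)
            if sel.sum() == 0:
                continue
            fracs.append(np.mean(np.abs(lickpos[sel] - zone_center) <= 0.25))
        return float(np.mean(fracs))

    def test_zero_learning_stays_at_chance(self):
        fr = np.mean(
            [
                self._probe_zone_fraction(
                    synth.synth_lick_protocol("A", learning_rate=0.0, seed=s)[0], 0.5
                )
                for s in range(4)
            ]
        )
        assert fr == pytest.approx(CHANCE_ZONE_FRACTION, abs=0.06)

    def test_learning_detected_by_mann_whitney(self):
        # 5 learned mice vs 5 naive: zone preference differs on probe trials
        learned = [
            self._probe_zone_fraction(
                synth.synth_lick_protocol("A", learning_rate=1.0, seed=s)[0], 0.5
            )
            for s in range(5)
        ]
        naive = [
            self._probe_zone_fraction(
                synth.synth_lick_protocol("A", learning_rate=0.0, seed=50 + s)[0], 0.5
            )
            for s in range(5)
        ]
        _, p = mann_whitney_u(learned, naive)
        assert p < 0.05

    def test_day1_only_auto_rewards(self):
        days, truth = synth.synth_lick_protocol("B", seed=1)
        d1 = days[0]
        rewards = [e for e in d1["events"] if e[1] == "reward"]
        assert all(e[2] == truth["zone_center_m"] for e in rewards)
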