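"""Harrell-Davis estimation, shift functions, effect sizes, permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeforge.shifts import (
    eta_sq_epsilon_sq,
    hd_deciles,
    hd_quantile,
    hd_weights,
    hedges_g,
    hochberg,
    learning_slope,
    permute_within_condition,
    shift_function,
)

from _oracles import hd_quantile_direct, hd_weights_direct


class TestHarrellDavis:
    def test_constant_sample_returns_constant(self):
        assert hd_quantile(np.full(17, 3.2), 0.3) == pytest.approx(3.2)

    def test_symmetric_sample_median_is_center(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        assert hd_quantile(x, 0.5) == pytest.approx(4.0)

    def test_median_of_1_to_5_matches_direct_weight_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert hd_quantile(x, 0.5) == pytest.approx(
            hd_quantile_direct(x, 0.5), abs=1e-12
        )

    @pytest.mark.parametrize("n", [2, 5, 11, 50])
    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.9])
    def test_weights_match_direct_loop_and_sum_to_one(self, n, q):
        w = hd_weights(n, q)
        np.testing.assert_allclose(w, hd_weights_direct(n, q), atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(min_value=2, max_value=60), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_deciles_monotone_in_q(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        d = hd_deciles(x)
        assert (np.diff(d) >= -1e-12).all()

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hd_quantile(np.array([1.0]), 0.5)
        with pytest.raises(ValueError):
            hd_quantile(np.array([1.0, 2.0]), 1.5)


class TestShiftFunction:
    def test_self_comparison_is_null(self, rng):
        x = rng.normal(size=40)
        sf = shift_function(x, x, n_boot=500, rng=rng)
        np.testing.assert_allclose(sf.differences, 0.0, atol=1e-12)
        assert not sf.significant.any()

    def test_location_shift_recovers_offset_everywhere(self, rng):
        a = rng.normal(size=100)
        sf = shift_function(a, a + 3.0, n_boot=1000, rng=rng)
        np.testing.assert_allclose(sf.differences, 3.0, atol=1e-12)
        assert (sf.ci_low > 0).all()  # all deciles significantly shifted
        assert sf.significant.all()

    def test_decilewise_antisymmetry(self, rng):
        a, b = rng.normal(size=60), rng.normal(1.0, 2.0, size=60)
        ab = shift_function(a, b, n_boot=400, seed=5)
        ba = shift_function(b, a, n_boot=400, seed=5)
        np.testing.assert_allclose(ab.differences, -ba.differences, atol=1e-12)

    def test_point_estimate_inside_interval(self, rng):
        for _ in range(5):
            a = rng.standard_t(3, size=25)
            b = rng.standard_t(3, size=30) + rng.normal()
            sf = shift_function(a, b, n_boot=300, rng=rng)
            assert (sf.ci_low <= sf.differences + 1e-12).all()
            assert (sf.differences <= sf.ci_high + 1e-12).all()

    def test_degenerate_constant_samples_flagged(self):
        with pytest.warns(UserWarning):
            sf = shift_function(np.full(12, 2.0), np.full(15, 2.0), n_boot=200,
                                seed=0)
        assert sf.degenerate
        np.testing.assert_allclose(sf.ci_low, sf.ci_high, atol=1e-12)

    def test_small_sample_warns(self, rng):
        with pytest.warns(UserWarning, match="fewer than 10"):
            shift_function(rng.normal(size=5), rng.normal(size=5), n_boot=100,
                           rng=rng)

    def test_seeded_reproducibility(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        s1 = shift_function(a, b, n_boot=300, seed=42)
        s2 = shift_function(a, b, n_boot=300, seed=42)
        np.testing.assert_array_equal(s1.ci_low, s2.ci_low)
        np.testing.assert_array_equal(s1.p_values, s2.p_values)

    def test_bootstrap_ci_coverage_for_location_shift(self):
        """Percentile-bootstrap CI covers the true decile difference (a pure
        location shift) at close to nominal rate, per decile."""
        rng = np.random.default_rng(2027)
        n_sims, shift = 500, 3.0
        covered = np.zeros(9)
        for _ in range(n_sims):
            a = rng.normal(size=100)
            b = rng.normal(size=100) + shift
            sf = shift_function(a, b, n_boot=2000, rng=rng)
            covered += (sf.ci_low <= shift) & (shift <= sf.ci_high)
        rates = covered / n_sims
        assert (rates >= 0.92).all() and (rates <= 0.98).all()


class TestHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(hochberg(np.array([0.03])), [0.03])

    def test_known_stepup_example(self):
        p = np.array([0.01, 0.02, 0.04])
        # ranks descending: 0.04 -> 0.04; 0.02 -> min(0.04, 2*0.02)=0.04;
        # 0.01 -> min(0.04, 3*0.01)=0.03
        np.testing.assert_allclose(hochberg(p), [0.03, 0.04, 0.04])

    def test_adjusted_never_smaller_than_raw(self, rng):
        p = rng.random(9)
        assert (hochberg(p) >= p - 1e-12).all()


class TestHedgesG:
    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=10)
        assert hedges_g(x, x.copy()) == pytest.approx(0.0)

    def test_antisymmetric_under_swap(self, rng):
        a, b = rng.normal(size=8), rng.normal(0.5, 1.3, size=12)
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_five_point_samples_match_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        df = 8
        pooled = np.sqrt(
            (4 * a.var(ddof=1) + 4 * b.var(ddof=1)) / df
        )
        expected = (1 - 3 / (4 * df - 1)) * (a.mean() - b.mean()) / pooled
        assert hedges_g(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(np.full(5, 1.0), np.full(5, 2.0))


class TestEtaEpsilon:
    def test_identical_group_means_give_near_zero_eta(self, rng):
        g = [rng.normal(size=200) for _ in range(3)]
        es = eta_sq_epsilon_sq(g)
        assert es.eta_squared < 0.03

    def test_fully_separated_groups_approach_one(self):
        g = [
            np.array([1.0, 1.001, 0.999]),
            np.array([5.0, 5.001, 4.999]),
            np.array([9.0, 9.001, 8.999]),
        ]
        es = eta_sq_epsilon_sq(g)
        assert es.eta_squared > 0.999

    def test_toy_groups_match_brute_force(self, rng):
        from scipy.stats import kruskal

        groups = [rng.normal(m, 1, size=4) for m in (0, 1, 2)]
        es = eta_sq_epsilon_sq(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_b = sum(4 * (g.mean() - grand) ** 2 for g in groups)
        ss_t = ((allv - grand) ** 2).sum()
        assert es.eta_squared == pytest.approx(ss_b / ss_t, abs=1e-12)
        H = kruskal(*groups).statistic
        n = 12
        assert es.epsilon_squared == pytest.approx(
            H / ((n**2 - 1) / (n + 1)), abs=1e-12
        )

    def test_all_identical_guarded(self):
        with pytest.warns(UserWarning):
            es = eta_sq_epsilon_sq([np.ones(4), np.ones(4)])
        assert es.degenerate and es.eta_squared == 0.0


class TestLearningSlope:
    def test_exact_linear_in_sqrt_hours(self):
        hours = np.array([0.0, 25.0, 100.0])
        scores = 1.0 + 2.0 * np.sqrt(hours)
        ls = learning_slope(hours, scores, "S01")
        assert ls.slope == pytest.approx(2.0)
        assert ls.intercept == pytest.approx(1.0)

    def test_constant_scores_flat_slope(self):
        ls = learning_slope([0, 50, 100], [5.0, 5.0, 5.0])
        assert ls.slope == pytest.approx(0.0)

    def test_noisy_subject_matches_normal_equations(self, rng):
        hours = np.array([0.0, 50.0, 100.0, 30.0, 80.0])
        scores = 2 + 0.8 * np.sqrt(hours) + rng.normal(0, 0.3, 5)
        ls = learning_slope(hours, scores)
        X = np.column_stack([np.ones(5), np.sqrt(hours)])
        beta = np.linalg.solve(X.T @ X, X.T @ scores)
        assert ls.slope == pytest.approx(beta[1], abs=1e-10)

    def test_single_hour_value_rejected(self):
        with pytest.raises(ValueError):
            learning_slope([50.0, 50.0], [1.0, 2.0])


class TestPermuteWithinCondition:
    def _table(self):
        rows = []
        for sess in ("Pre", "Post1"):
            for subj in ("S01", "S02", "S03"):
                for win in (0, 1):
                    rows.append((subj, sess, win, hash((subj, sess, win)) % 97))
        return pd.DataFrame(rows, columns=["subject", "session", "window", "v"])

    def test_single_subject_permutation_is_identity(self):
        df = self._table()
        df = df[df["subject"] == "S01"]
        permuted, means = permute_within_condition(df, seed=0)
        pd.testing.assert_frame_equal(
            permuted.reset_index(drop=True), df.reset_index(drop=True)
        )

    def test_sessionwise_grand_mean_invariant(self):
        df = self._table()
        for seed in range(5):
            _, means = permute_within_condition(df, seed=seed)
            for sess in ("Pre", "Post1"):
                assert means[means["session"] == sess]["v"].mean() == \
                    pytest.approx(df[df["session"] == sess]["v"].mean())

    def test_fixed_seed_matches_hand_shuffle(self):
        df = self._table()
        seed = 13
        permuted, means = permute_within_condition(df, seed=seed)
        # replicate the documented construction by hand
        rng = np.random.default_rng(seed)
        expected = df.copy()
        for sess in sorted(df["session"].unique()):
            mask = expected["session"] == sess
            subjects = sorted(expected.loc[mask, "subject"].unique())
            perm = rng.permutation(len(subjects))
            mapping = {subjects[i]: subjects[perm[i]] for i in range(3)}
            expected.loc[mask, "subject"] = expected.loc[mask, "subject"].map(
                mapping
            )
        pd.testing.assert_frame_equal(permuted, expected)
        hand_means = (
            expected.groupby(["subject", "session"], sort=True)[["v"]]
            .mean()
            .reset_index()
        )
        pd.testing.assert_frame_equal(means, hand_means)

    def test_missing_cells_listed(self):
        df = self._table().iloc[1:]
        with pytest.raises(ValueError, match="missing cells"):
            permute_within_condition(df, seed=0)
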