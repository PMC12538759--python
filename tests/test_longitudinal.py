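"""Repeated-measures statistics: RM-ANOVA equivalence, GG epsilon,
Dunnett adjustment, BKY FDR, biomarker transforms, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from remap.longitudinal import (
    BiomarkerSeries,
    LongitudinalOutcome,
    bky_two_stage,
    correlate_differentials,
    dunnett_baseline_comparisons,
    fit_time_effect,
    gg_epsilon,
    log2_series,
    residual_qq,
)

TPS = ["BSL", "T1", "T2", "T3"]


def rm_anova_oracle_f(Y):
    """Textbook sums-of-squares repeated-measures ANOVA F for the time
    effect (independent of the model-based implementation)."""
    n, k = Y.shape
    grand = Y.mean()
    ss_time = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    ms_time = ss_time / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_time / ms_err


def outcome_from(Y, name="y"):
    return LongitudinalOutcome(name, pd.DataFrame(Y, columns=TPS[: Y.shape[1]]))


class TestTimeEffect:
    def test_balanced_equals_sums_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            Y = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
            res = fit_time_effect(outcome_from(Y))
            assert res.f_stat == pytest.approx(rm_anova_oracle_f(Y), abs=1e-8)

    def test_constant_shift_at_t3_with_no_noise_is_certain(self):
        base = np.tile(np.arange(10.0)[:, None], (1, 4))
        base[:, 3] += 5.0
        res = fit_time_effect(outcome_from(base))
        assert res.f_stat > 1e6
        assert res.p_value < 1e-12

    def test_constant_data_gives_f_zero_p_one(self):
        Y = np.full((8, 4), 3.0)
        res = fit_time_effect(outcome_from(Y))
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_too_few_timepoints_errors(self):
        Y = np.random.default_rng(1).normal(size=(8, 1))
        with pytest.raises(ValueError):
            fit_time_effect(outcome_from(Y))

    def test_missing_data_path_close_to_complete_fit(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(30, 4)) + rng.normal(size=(30, 1))
        Y[:, 3] += 1.5
        full = fit_time_effect(outcome_from(Y))
        Ym = Y.copy()
        Ym[::9, 2] = np.nan  # sprinkle missing cells
        part = fit_time_effect(outcome_from(Ym))
        assert part.f_stat == pytest.approx(full.f_stat, rel=0.25)
        assert part.p_value < 0.01

    def test_gg_scaled_dfs_reported(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(20, 4))
        res = fit_time_effect(outcome_from(Y))
        assert res.df_num == pytest.approx(res.epsilon * 3)
        assert 1 / 3 <= res.epsilon <= 1


class TestGGEpsilon:
    def test_two_levels_always_spherical(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_compound_symmetry_gives_one(self):
        k = 4
        S = np.full((k, k), 0.6) + np.eye(k) * 1.4
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_random_spd_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            k = int(rng.integers(3, 6))
            A = rng.normal(size=(k, k))
            S = A @ A.T + 0.5 * np.eye(k)
            # oracle: classical formula from double-centered eigenvalues
            C = np.eye(k) - np.ones((k, k)) / k
            lam = np.linalg.eigvalsh(C @ S @ C)
            expected = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
            expected = np.clip(expected, 1 / (k - 1), 1.0)
            assert gg_epsilon(S) == pytest.approx(expected, abs=1e-10)

    def test_not_psd_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            gg_epsilon(S)


class TestDunnett:
    def test_single_comparison_equals_paired_t(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(15, 2))
        Y[:, 1] += 0.8
        results = dunnett_baseline_comparisons(outcome_from(Y))
        assert len(results) == 1
        r = results[0]
        d = Y[:, 1] - Y[:, 0]
        t, p = stats.ttest_rel(Y[:, 1], Y[:, 0])
        assert r.p_adjusted == pytest.approx(p, abs=1e-12)
        assert r.mean_change == pytest.approx(d.mean())

    def test_sandwich_raw_le_adjusted_le_bonferroni(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            Y = rng.normal(size=(12, 4)) + rng.normal(0, 0.5, size=(12, 1))
            results = dunnett_baseline_comparisons(outcome_from(Y), seed=1)
            k = len(results)
            for r in results:
                assert r.p_raw <= r.p_adjusted + 1e-12
                assert r.p_adjusted <= min(1.0, k * r.p_raw) + 1e-12
                assert r.ci_low <= r.mean_change <= r.ci_high

    def test_simultaneous_ci_wider_than_pointwise(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(20, 4))
        results = dunnett_baseline_comparisons(outcome_from(Y), seed=2)
        assert len(results) == 3
        for j, r in enumerate(results, start=1):
            d = Y[:, j] - Y[:, 0]
            se = d.std(ddof=1) / np.sqrt(len(d))
            crit = ((r.ci_high - r.ci_low) / 2) / se
            assert crit > stats.t.ppf(0.975, r.n_pairs - 1)  # many-to-one
            assert crit < stats.t.ppf(1 - 0.05 / (2 * 3), r.n_pairs - 1) + 0.02

    def test_tiny_timepoint_dropped_with_warning(self):
        Y = np.random.default_rng(8).normal(size=(10, 3))
        Y[1:, 2] = np.nan  # only one pair left at T2
        with pytest.warns(UserWarning, match="paired"):
            results = dunnett_baseline_comparisons(outcome_from(Y))
        assert [r.timepoint for r in results] == ["T1"]


class TestBKY:
    def test_all_tiny_pvalues_all_rejected(self):
        out = bky_two_stage([1e-9] * 10)
        assert out["rejected"].all()

    def test_two_large_pvalues_nothing_rejected(self):
        out = bky_two_stage([0.2, 0.8])
        assert not out["rejected"].any()
        assert (out["q_values"] > 0.05).all()

    def test_mixed_case_hand_executed(self):
        # stage 1 at alpha' = 0.05/1.05 rejects the two tiny p's (r1 = 2),
        # m0 = 2, stage 2 runs BH at alpha' * 4 / 2
        p = [1e-4, 5e-4, 0.3, 0.7]
        out = bky_two_stage(p)
        assert list(out["rejected"]) == [True, True, False, False]
        assert out["m0_hat"] == 2

    def test_matches_statsmodels_tsbky_rejections(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(20):
            m = int(rng.integers(3, 40))
            p = np.concatenate(
                [rng.uniform(0, 1, m), rng.uniform(0, 1e-3, int(rng.integers(0, 4)))]
            )
            ours = bky_two_stage(p)["rejected"]
            theirs = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(ours, theirs)

    def test_empty_input(self):
        out = bky_two_stage([])
        assert len(out["q_values"]) == 0

    def test_rejection_iff_q_below_alpha_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=80, deadline=None)
        @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
        def check(p):
            out = bky_two_stage(p, alpha=0.05)
            q = out["q_values"]
            assert ((q >= 0) & (q <= 1)).all()
            # the two-stage step-up rejects exactly the q <= alpha set
            assert np.array_equal(out["rejected"], q <= 0.05)
            # q ordering follows p ordering
            order = np.argsort(p, kind="stable")
            assert (np.diff(q[order]) >= -1e-12).all()

        check()

    def test_out_of_range_pvalue_rejected(self):
        with pytest.raises(ValueError):
            bky_two_stage([0.5, 1.2])


class TestLog2Series:
    def wide(self, arr):
        return pd.DataFrame(arr, columns=TPS[: np.asarray(arr).shape[1]])

    def test_constant_series_fold_one(self):
        s = BiomarkerSeries("x", self.wide(np.full((6, 4), 100.0)))
        out = log2_series(s)
        for tp in ("T1", "T2", "T3"):
            assert out["fold_changes"][tp]["fold_change"] == pytest.approx(1.0)

    def test_doubling_gives_mean_log2_diff_one(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(50, 150, 8)
        arr = np.column_stack([base, base, base, 2 * base])
        out = log2_series(BiomarkerSeries("x", self.wide(arr)))
        assert out["fold_changes"]["T3"]["mean_log2_diff"] == pytest.approx(1.0)
        assert out["fold_changes"]["T3"]["fold_change"] == pytest.approx(2.0)

    def test_lognormal_matches_geometric_mean_ratio_oracle(self):
        rng = np.random.default_rng(11)
        arr = np.exp(rng.normal(4, 0.5, size=(30, 4)))
        out = log2_series(BiomarkerSeries("x", self.wide(arr)))
        for j, tp in enumerate(("T1", "T2", "T3"), start=1):
            gmr = np.exp(np.mean(np.log(arr[:, j] / arr[:, 0])))
            assert out["fold_changes"][tp]["fold_change"] == pytest.approx(gmr)

    def test_detection_floor_substitution_flagged(self):
        arr = np.array([[100.0, 1.0, 120.0, 130.0], [90.0, 95.0, 85.0, 80.0]])
        s = BiomarkerSeries("x", self.wide(arr), detection_floor=2.0)
        out = log2_series(s)
        assert out["floored"].iloc[0, 1]
        assert out["log2"].iloc[0, 1] == pytest.approx(np.log2(1.0))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            BiomarkerSeries("x", self.wide(np.array([[-1.0, 2.0]])))


class TestCorrelate:
    def test_perfect_monotone_gives_plus_minus_one(self):
        x = pd.Series([1.0, 2, 3, 4, 5, 6])
        assert correlate_differentials(x, x).rs == pytest.approx(1.0)
        assert correlate_differentials(-x, x).rs == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(12)
        x = pd.Series(rng.integers(0, 4, 20).astype(float))
        y = pd.Series(rng.integers(0, 4, 20).astype(float))
        entry = correlate_differentials(y, x)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert entry.rs == pytest.approx(oracle, abs=1e-12)

    def test_exact_small_n_p_for_perfect_correlation(self):
        # n=5, rs=1: only identity and reversal reach |rs| = 1 -> p = 2/5!
        x = pd.Series([1.0, 2, 3, 4, 5])
        entry = correlate_differentials(x, x)
        assert entry.p_value == pytest.approx(2 / 120)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(13)
        x = pd.Series(rng.normal(size=40))
        y = x * 0.5 + pd.Series(rng.normal(size=40))
        entry = correlate_differentials(y, x)
        ref = stats.spearmanr(x, y)
        assert entry.rs == pytest.approx(ref.statistic, abs=1e-12)
        assert entry.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_insufficient_pairs_flagged(self):
        x = pd.Series([1.0, 2, np.nan, np.nan, np.nan])
        entry = correlate_differentials(x, x)
        assert entry.rs is None and "pairs" in entry.flag

    def test_zero_variance_flagged(self):
        x = pd.Series([1.0, 1, 1, 1, 1])
        y = pd.Series([1.0, 2, 3, 4, 5])
        entry = correlate_differentials(x, y)
        assert entry.rs is None and "variance" in entry.flag


class TestQQ:
    def test_symmetric_residuals_antisymmetric_table(self):
        r = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        qq = residual_qq(r)
        assert np.allclose(qq["observed"].to_numpy(),
                           -qq["observed"].to_numpy()[::-1])
        assert np.allclose(qq["theoretical"].to_numpy(),
                           -qq["theoretical"].to_numpy()[::-1])

    def test_three_residuals_three_rows(self):
        assert len(residual_qq([0.1, -0.2, 0.4])) == 3

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            residual_qq([0.1, 0.2])
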