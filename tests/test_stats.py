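"""Regression models, likelihood-ratio test, group tests, normalization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import myoslice as ms


class TestLinearFit:
    def test_noiseless_line_exact(self):
        x = np.linspace(0, 5, 12)
        fit = ms.linear_fit(x, 2 * x + 1)
        assert fit.params[1] == pytest.approx(2.0, abs=1e-10)
        assert fit.params[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_covariance_flat_fit(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        fit = ms.linear_fit(x, y)
        assert fit.params[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.f_stat == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == pytest.approx(1.0, abs=1e-9)

    def test_slope_ci_coverage(self):
        # nominal 95% CI for the slope should cover the truth >= 90% of reps
        rng = np.random.default_rng(123)
        n, covered, reps = 20, 0, 500
        for _ in range(reps):
            x = rng.uniform(0, 1, n)
            y = 3.0 - 1.5 * x + rng.normal(0, 0.1, n)
            fit = ms.linear_fit(x, y)
            half = sps.t.ppf(0.975, n - 2) * fit.bse[1]
            covered += abs(fit.params[1] - (-1.5)) <= half
        assert covered / reps >= 0.90

    def test_conf_band_contains_mean_response(self):
        x = np.linspace(0, 1, 30)
        rng = np.random.default_rng(0)
        fit = ms.linear_fit(x, 1 + 2 * x + rng.normal(0, 0.05, 30))
        import statsmodels.api as sm

        band = fit.conf_band(sm.add_constant(np.array([0.2, 0.8])))
        assert band.shape == (2, 2)
        assert (band[:, 0] < band[:, 1]).all()

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.linear_fit(np.ones(5), np.arange(5.0))
        with pytest.raises(ms.InvalidSpecError):
            ms.linear_fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestInteractionFit:
    def test_noiseless_cohort_recovers_printed_form_exactly(self):
        df, _ = ms.gen_cohort(n_samples=40, ttr_noise_sd=0.0, rng_seed=8)
        fit = ms.interaction_fit(
            df["delta_tt_um"].to_numpy(), df["ncx1"].to_numpy(), df["ttr_1hz_s"].to_numpy()
        )
        assert fit.reparam["b1"] == pytest.approx(0.36, abs=1e-10)
        assert fit.reparam["interaction_ratio"] == pytest.approx(0.069, abs=1e-10)
        assert fit.r2_kind == "uncentered"

    def test_zero_ncx_reduces_to_univariate_no_intercept(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.8, 1.5, 30)
        y = 0.4 * d + rng.normal(0, 0.01, 30)
        fit = ms.interaction_fit(d, np.zeros(30), y)
        expected = float(np.dot(d, y) / np.dot(d, d))
        assert fit.params[0] == pytest.approx(expected, abs=1e-12)

    def test_sample_order_invariance(self):
        df, _ = ms.gen_cohort(n_samples=25, rng_seed=3)
        perm = np.random.default_rng(0).permutation(25)
        a = ms.interaction_fit(
            df["delta_tt_um"].to_numpy(), df["ncx1"].to_numpy(), df["ttr_1hz_s"].to_numpy()
        )
        b = ms.interaction_fit(
            df["delta_tt_um"].to_numpy()[perm],
            df["ncx1"].to_numpy()[perm],
            df["ttr_1hz_s"].to_numpy()[perm],
        )
        np.testing.assert_allclose(a.params, b.params, rtol=1e-9)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.interaction_fit(np.zeros(10), np.ones(10), np.ones(10))
        with pytest.raises(ms.InvalidSpecError):
            ms.interaction_fit(np.ones(10), np.ones(10), np.ones(10))  # collinear

    def test_full_r2_at_least_reduced_r2(self):
        df, _ = ms.gen_cohort(n_samples=30, rng_seed=5)
        d = df["delta_tt_um"].to_numpy()
        y = df["ttr_1hz_s"].to_numpy()
        full = ms.interaction_fit(d, df["ncx1"].to_numpy(), y)
        reduced = ms.interaction_fit(d, np.zeros_like(d), y)
        assert full.r2 >= reduced.r2 - 1e-12


class TestLikelihoodRatio:
    def _fits(self, n=40, b_ratio=0.069, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.8, 1.5, n)
        x = rng.uniform(0.2, 3.0, n)
        y = 0.36 * (d - b_ratio * x * d) + rng.normal(0, noise, n)
        full = ms.interaction_fit(d, x, y)
        reduced = ms.interaction_fit(d, np.zeros(n), y)
        return full, reduced

    def test_identical_models_no_evidence(self):
        full, _ = self._fits()
        assert ms.likelihood_ratio_test(full, full) == (0.0, 1.0)

    def test_nonnested_rss_ordering_guarded(self):
        full, reduced = self._fits()
        swapped_full = reduced
        with pytest.raises(ms.InvalidSpecError):
            ms.likelihood_ratio_test(swapped_full, full)

    def test_strong_interaction_detected(self):
        full, reduced = self._fits(n=60, b_ratio=0.2, noise=0.005)
        lr, p = ms.likelihood_ratio_test(full, reduced)
        assert lr > 0 and p < 0.01

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(2024)
        reps, rejections, n = 1000, 0, 100
        for _ in range(reps):
            d = rng.uniform(0.8, 1.5, n)
            x = rng.uniform(0.2, 3.0, n)
            y = 0.36 * d + rng.normal(0, 0.02, n)
            full = ms.interaction_fit(d, x, y)
            reduced = ms.interaction_fit(d, np.zeros(n), y)
            _, p = ms.likelihood_ratio_test(full, reduced)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestGroupTests:
    def test_identical_groups_p_one(self):
        t, p = ms.t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self):
        a, b = [1.0, 2.0, 2.5], [1.4, 2.2, 3.3]
        _, p1 = ms.t_test_unpaired(a, b)
        _, p2 = ms.t_test_unpaired(b, a)
        assert p1 == pytest.approx(p2)

    def test_large_shift_highly_significant(self):
        a = [1.0, 2.0, 3.0]
        b = [101.0, 102.0, 103.0]
        _, p = ms.t_test_unpaired(a, b)
        assert p < 1e-3

    def test_zero_variance_equal_means(self):
        assert ms.t_test_unpaired([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_welch_variant_available(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 10)
        _, p_student = ms.t_test_unpaired(a, b)
        _, p_welch = ms.t_test_unpaired(a, b, welch=True)
        assert p_student != p_welch


class TestHolm:
    def test_hand_computed_vectors(self):
        np.testing.assert_allclose(ms.holm_bonferroni([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(ms.holm_bonferroni([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ms.holm_bonferroni([0.2]), [0.2])

    @given(
        ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=8)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, ps):
        adj = ms.holm_bonferroni(ps)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.holm_bonferroni([0.1, 1.5])


class TestDichotomize:
    def test_split_and_boundary_assignment(self):
        df = pd.DataFrame({"delta_tt_um": [0.9, 1.2, 1.05]})
        low, high = ms.dichotomize_by_dtt(df)
        assert low["delta_tt_um"].tolist() == [0.9]
        assert sorted(high["delta_tt_um"]) == [1.05, 1.2]  # boundary goes severe

    def test_empty_input_gives_two_empty_groups(self):
        df = pd.DataFrame({"delta_tt_um": []})
        low, high = ms.dichotomize_by_dtt(df)
        assert low.empty and high.empty

    def test_undefined_dtt_rejected(self):
        df = pd.DataFrame({"delta_tt_um": [1.0, np.nan]})
        with pytest.raises(ms.InvalidSpecError):
            ms.dichotomize_by_dtt(df)


class TestDensitometry:
    def test_arithmetic(self):
        assert ms.normalize_densitometry(4.0, 4.0, 1.0, reference=2.0) == pytest.approx(1.0)

    def test_reference_lane_normalizes_to_one(self):
        ref = 5.0 / np.sqrt(2.0 * 3.0)
        assert ms.normalize_densitometry(5.0, 2.0, 3.0, reference=ref) == pytest.approx(1.0)

    def test_gel_exposure_invariance(self):
        k = 3.7
        a = ms.normalize_densitometry(4.0, 2.0, 2.0, reference=1.5)
        b = ms.normalize_densitometry(k * 4.0, k * 2.0, k * 2.0, reference=1.5 * np.sqrt(k) / np.sqrt(k))
        # raw scales k, loading normalizer scales k -> ratio invariant
        assert ms.normalize_densitometry(k * 4.0, k * 2.0, k * 2.0, reference=1.5) == pytest.approx(a)
        assert b == pytest.approx(a)

    def test_nonpositive_rejected(self):
        with pytest.raises(ms.InvalidSpecError):
            ms.normalize_densitometry(0.0, 1.0, 1.0)


class TestFrequencyGroupComparison:
    def _records(self, effect_freqs=(), n=7, seed=0):
        rng = np.random.default_rng(seed)
        rows = {"delta_tt_um": np.r_[np.full(n, 0.9), np.full(n, 1.3)]}
        for f_hz, col in (
            (0.2, "tension_0p2_mN_mm2"),
            (0.5, "tension_0p5_mN_mm2"),
            (1.0, "tension_1_mN_mm2"),
            (2.0, "tension_2_mN_mm2"),
        ):
            base = rng.normal(1.5, 0.1, 2 * n)
            if f_hz in effect_freqs:
                base[n:] -= 0.3  # 3 x SD shift in the severe group
            rows[col] = base
        return pd.DataFrame(rows)

    def test_no_effect_gives_nonsignificant_everywhere(self):
        out = ms.frequency_group_comparison(self._records())
        assert (out["p_holm"] > 0.05).all()
        assert len(out) == 4 and list(out["frequency_hz"]) == [0.2, 0.5, 1.0, 2.0]

    def test_effect_only_at_high_frequencies_detected_there_only(self):
        out = ms.frequency_group_comparison(self._records(effect_freqs=(1.0, 2.0), seed=1))
        sig = out.set_index("frequency_hz")["p_holm"] < 0.05
        assert sig[1.0] and sig[2.0]
        assert not sig[0.2] and not sig[0.5]

    def test_single_sided_group_rejected(self):
        df = self._records()
        df = df[df["delta_tt_um"] < 1.05]
        with pytest.raises(ms.InvalidSpecError):
            ms.frequency_group_comparison(df)
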