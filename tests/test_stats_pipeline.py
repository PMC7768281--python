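import numpy as np
import pandas as pd
import pytest

from ratiospec import (block_differences, bootstrap_ci, bootstrap_diff_corr,
                       spearman, topography_correlation)
from ratiospec.stats_pipeline import (age_correlation_suite,
                                      ratio_param_correlation_table)


def hand_spearman(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for untied data: the textbook formula."""
    xr = np.argsort(np.argsort(x))
    yr = np.argsort(np.argsort(y))
    d2 = np.sum((xr - yr) ** 2)
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))


class TestSpearman:
    def test_monotone_pairings(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        assert spearman(x, y) == pytest.approx(0.8)
        assert spearman(x, y) == pytest.approx(hand_spearman(x, y))

    def test_matches_hand_formula_on_random_untied_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.permutation(20).astype(float)
            y = rng.permutation(20).astype(float)
            assert spearman(x, y) == pytest.approx(hand_spearman(x, y))

    def test_zero_variance_undefined(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_missing_pairs_removed_listwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, np.nan, 5.0]
        assert spearman(x, y) == pytest.approx(1.0)


class TestBootstrapCi:
    def test_perfectly_monotone_data_pins_ci_at_one(self):
        x = np.arange(20.0)
        res = bootstrap_ci(x, x ** 3, n_resamples=200, seed=0)
        assert res.rho == 1.0
        assert res.ci_low == pytest.approx(1.0, abs=1e-9)
        assert res.ci_high == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = bootstrap_ci(x, y, n_resamples=300, seed=42)
        b = bootstrap_ci(x, y, n_resamples=300, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_bounds_ordered_and_in_range(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = bootstrap_ci(x, y, n_resamples=500, seed=3)
        assert -1.0 <= res.ci_low <= res.rho <= res.ci_high <= 1.0

    def test_coverage_of_sample_rho_across_replications(self):
        # the percentile interval should almost always contain the
        # full-sample statistic itself
        rng = np.random.default_rng(4)
        hits = 0
        for i in range(100):
            x = rng.normal(size=60)
            y = 0.6 * x + 0.8 * rng.normal(size=60)
            res = bootstrap_ci(x, y, n_resamples=200, seed=i)
            hits += res.ci_low <= res.rho <= res.ci_high
        assert hits >= 94


class TestBootstrapDiffCorr:
    def test_identical_variables_give_null_result(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = bootstrap_diff_corr(x, y, y, n_resamples=300, seed=0)
        assert res.delta_rho == 0.0
        assert res.p >= 0.95

    def test_signal_vs_noise_rejects(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        noise = rng.normal(size=100)
        res = bootstrap_diff_corr(x, x, noise, n_resamples=500, seed=1)
        assert res.p < 0.05
        assert res.delta_rho > 0.5

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(7)
        x, y1, y2 = (rng.normal(size=30) for _ in range(3))
        a = bootstrap_diff_corr(x, y1, y2, n_resamples=200, seed=9)
        b = bootstrap_diff_corr(x, y1, y2, n_resamples=200, seed=9)
        assert a == b

    def test_absolute_mode_compares_magnitudes(self):
        x = np.arange(50.0)
        rng = np.random.default_rng(8)
        y1 = -x + rng.normal(0, 5, 50)      # strong negative
        y2 = x + rng.normal(0, 40, 50)      # weak positive
        res = bootstrap_diff_corr(x, y1, y2, use_absolute=True,
                                  n_resamples=300, seed=2)
        assert res.delta_rho > 0          # |rho1| > |rho2|


class TestBlockDifferences:
    def test_constant_blocks_all_zero(self):
        series = block_differences(np.ones((3, 5)))
        assert np.all(series.diffs == 0.0)

    def test_five_blocks_give_four_differences(self):
        series = block_differences(np.arange(10.0).reshape(2, 5))
        assert series.diffs.shape == (2, 4)

    def test_arithmetic(self):
        series = block_differences([[1.0, 3.0, 2.0]])
        assert series.diffs.tolist() == [[2.0, -1.0]]
        assert series.pooled().tolist() == [2.0, -1.0]

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_differences([[1.0]])


class TestCorrelationTables:
    @staticmethod
    def _measures(n=40, seed=0):
        rng = np.random.default_rng(seed)
        exponent = rng.normal(1.5, 0.3, n)
        tbr = np.exp(exponent) * (1 + 0.01 * rng.normal(size=n))
        return pd.DataFrame({
            "subject": np.arange(n), "age": rng.uniform(6, 44, n),
            "theta/beta": tbr, "theta/alpha": rng.lognormal(size=n),
            "alpha/beta": rng.lognormal(size=n),
            "exponent": exponent, "theta_pw": np.full(n, np.nan),
            "alpha_pw": rng.normal(0.7, 0.2, n)})

    def test_exponent_dominated_table_cell(self):
        table = ratio_param_correlation_table(
            self._measures(), parameters=("theta_pw", "alpha_pw", "exponent"),
            n_resamples=200, seed=0)
        cell = table[(table.measure == "theta/beta")
                     & (table.parameter == "exponent")].iloc[0]
        assert cell.rho > 0.99
        # all-missing parameter yields an absent (NaN) cell, not a crash
        missing = table[(table.measure == "theta/beta")
                        & (table.parameter == "theta_pw")].iloc[0]
        assert np.isnan(missing.rho)

    def test_zero_variance_cohort_all_absent(self):
        df = self._measures(10)
        for col in ("theta/beta", "theta/alpha", "alpha/beta"):
            df[col] = 1.0
        table = ratio_param_correlation_table(
            df, parameters=("exponent",), n_resamples=50, seed=0)
        assert table.rho.isna().all()

    def test_age_suite_null_when_shuffled(self):
        df = self._measures(60, seed=3)
        rng = np.random.default_rng(4)
        df["age"] = rng.permutation(df["age"].to_numpy())
        out = age_correlation_suite(df, columns=["theta/alpha", "alpha/beta"],
                                    n_resamples=300, seed=5)
        for _, row in out.iterrows():
            assert abs(row.rho) < 0.4
            assert row.ci_low <= 0.0 <= row.ci_high

    def test_age_suite_constant_age_absent(self):
        df = self._measures(10)
        df["age"] = 20.0
        out = age_correlation_suite(df, columns=["theta/beta"],
                                    n_resamples=50, seed=0)
        assert np.isnan(out.iloc[0].rho)


class TestTopography:
    def test_self_and_negated_maps(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=25)
        res = topography_correlation(a, a, n_resamples=100, seed=0)
        assert res.rho == pytest.approx(1.0)
        res = topography_correlation(a, -a, n_resamples=100, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_shared_gradient_drives_high_spatial_correlation(self):
        from ratiospec.cohort_synth import generate_cohort
        from ratiospec import CANONICAL_BANDS, compute_ratio
        from ratiospec.experiments import exponent_dominated_config
        config = exponent_dominated_config(n_subjects=15, n_channels=15)
        cohort = generate_cohort(config, seed=2)
        theta, beta = CANONICAL_BANDS["theta"], CANONICAL_BANDS["beta"]
        tbr_map = [np.mean([compute_ratio(cohort.spectrum(s, c, 0),
                                          theta, beta).value
                            for s in range(15)]) for c in range(15)]
        exp_map = (cohort.truth[cohort.truth.block == 0]
                   .groupby("channel")["exponent"].mean().to_numpy())
        res = topography_correlation(tbr_map, exp_map, n_resamples=200,
                                     seed=1)
        assert res.rho > 0.9
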