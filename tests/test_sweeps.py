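import numpy as np
import pytest

from ratiospec import (AperiodicParams, SpectralParams, SweepSpec,
                       TEN_PARAMETERS, count_affected_params,
                       default_base_params, paired_param_sweep,
                       single_param_sweep)
from ratiospec.sweeps import PARAMETER_GRIDS, apply_parameter, grid_values


class TestGrids:
    def test_grids_include_both_endpoints(self):
        for start, stop, inc in PARAMETER_GRIDS.values():
            vals = grid_values(start, stop, inc)
            assert vals[0] == start and vals[-1] == pytest.approx(stop)
            assert np.allclose(np.diff(vals), inc)

    @pytest.mark.parametrize("param,n", [("offset", 11), ("exponent", 16),
                                         ("theta_cf", 17), ("beta_cf", 18),
                                         ("theta_pw", 11), ("theta_bw", 2)])
    def test_grid_sizes(self, param, n):
        assert SweepSpec(param).values().size == n

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            apply_parameter(default_base_params(), "gamma_pw", 1.0)

    def test_missing_peak_rejected(self):
        base = SpectralParams(AperiodicParams(0.0, 1.0), (), 0.0)
        with pytest.raises(ValueError, match="no theta peak"):
            apply_parameter(base, "theta_pw", 0.5)


class TestSingleSweeps:
    def test_offset_sweep_leaves_all_ratios_unchanged(self):
        sweep = single_param_sweep(SweepSpec("offset"), noise_sd=0.0)
        for vals in sweep.ratios.values():
            assert (vals.max() - vals.min()) / vals.mean() <= 1e-9

    def test_theta_power_sweep_strictly_increases_tbr(self):
        sweep = single_param_sweep(SweepSpec("theta_pw"), noise_sd=0.0)
        assert np.all(np.diff(sweep.ratios["theta/beta"]) > 0)

    def test_exponent_sweep_strictly_increases_tbr(self):
        sweep = single_param_sweep(SweepSpec("exponent"), noise_sd=0.0)
        assert np.all(np.diff(sweep.ratios["theta/beta"]) > 0)

    def test_theta_cf_sweep_is_non_monotone(self):
        # at the printed 0.1 Hz default bandwidth the peak is narrower
        # than the 0.5 Hz bin spacing, so the sweep alternates between
        # on-bin and off-bin center frequencies
        tbr = single_param_sweep(SweepSpec("theta_cf"),
                                 noise_sd=0.0).ratios["theta/beta"]
        diffs = np.diff(tbr)
        assert np.any(diffs > 0) and np.any(diffs < 0)

    def test_wide_theta_peak_cf_sweep_rises_then_falls(self):
        # with a band-straddling width the peak enters the band, is best
        # captured mid-band, then its mass leaks toward the alpha edge
        base = default_base_params()
        for bw_param in ("theta_bw", "alpha_bw", "beta_bw"):
            base = apply_parameter(base, bw_param, 1.0)
        tbr = single_param_sweep(SweepSpec("theta_cf", base=base),
                                 noise_sd=0.0).ratios["theta/beta"]
        top = int(np.argmax(tbr))
        assert 0 < top < tbr.size - 1
        assert np.all(np.diff(tbr[:top + 1]) > 0)
        assert np.all(np.diff(tbr[top:]) < 0)

    def test_theta_and_beta_power_have_opposite_effects(self):
        up = single_param_sweep(SweepSpec("theta_pw"), noise_sd=0.0)
        down = single_param_sweep(SweepSpec("beta_pw"), noise_sd=0.0)
        tbr_up = up.ratios["theta/beta"]
        tbr_down = down.ratios["theta/beta"]
        assert tbr_up[-1] > tbr_up[0]
        assert tbr_down[-1] < tbr_down[0]

    def test_alpha_power_sweep_does_not_move_tbr(self):
        tbr = single_param_sweep(SweepSpec("alpha_pw"),
                                 noise_sd=0.0).ratios["theta/beta"]
        assert (tbr.max() - tbr.min()) / tbr.mean() < 1e-9

    def test_noise_free_sweeps_bit_reproducible(self):
        a = single_param_sweep(SweepSpec("exponent"), noise_sd=0.0)
        b = single_param_sweep(SweepSpec("exponent"), noise_sd=0.0)
        assert np.array_equal(a.ratios["theta/beta"], b.ratios["theta/beta"])


class TestPairedSweeps:
    def test_slice_at_default_matches_single_sweep_bitwise(self):
        grid = paired_param_sweep(SweepSpec("exponent"), SweepSpec("theta_pw"),
                                  noise_sd=0.0)
        single = single_param_sweep(SweepSpec("theta_pw"), noise_sd=0.0)
        at_default = np.flatnonzero(grid.values[0] == 1.0)[0]  # exponent 1
        assert np.array_equal(grid.ratios["theta/beta"][at_default],
                              single.ratios["theta/beta"])

    def test_cell_at_both_defaults_equals_baseline(self):
        grid = paired_param_sweep(SweepSpec("exponent"), SweepSpec("theta_pw"),
                                  noise_sd=0.0)
        baseline = single_param_sweep(
            SweepSpec("offset"), noise_sd=0.0).ratios["theta/beta"][0]
        i = np.flatnonzero(grid.values[0] == 1.0)[0]
        j = np.flatnonzero(np.isclose(grid.values[1], 0.5))[0]
        assert grid.ratios["theta/beta"][i, j] == pytest.approx(baseline,
                                                                rel=1e-12)

    def test_beta_power_decreases_tbr_within_each_exponent_row(self):
        grid = paired_param_sweep(SweepSpec("exponent"), SweepSpec("beta_pw"),
                                  noise_sd=0.0)
        tbr = grid.ratios["theta/beta"]
        assert np.all(np.diff(tbr, axis=1) < 0)

    def test_log_ratio_matrices_match_grid_shape(self):
        grid = paired_param_sweep(SweepSpec("exponent"), SweepSpec("theta_pw"),
                                  noise_sd=0.0)
        for mat in grid.log_ratios().values():
            assert mat.shape == (grid.values[0].size, grid.values[1].size)

    def test_identical_parameters_rejected(self):
        with pytest.raises(ValueError):
            paired_param_sweep(SweepSpec("exponent"), SweepSpec("exponent"))


class TestCensus:
    def test_ten_parameter_census_is_eight_with_stated_exceptions(self):
        count, verdicts = count_affected_params()
        assert count == 8
        assert not verdicts["offset"] and not verdicts["alpha_pw"]
        assert all(v for k, v in verdicts.items()
                   if k not in ("offset", "alpha_pw"))

    def test_pure_aperiodic_offset_only_census_is_zero(self):
        base = SpectralParams(AperiodicParams(0.0, 1.0), (), 0.0)
        count, _ = count_affected_params(base, parameters=("offset",))
        assert count == 0

    def test_single_parameter_census(self):
        count, _ = count_affected_params(parameters=("theta_pw",))
        assert count == 1

    def test_census_parameter_set_is_the_enumerated_ten(self):
        assert len(TEN_PARAMETERS) == 10
        assert "alpha_bw" not in TEN_PARAMETERS
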