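"""Chi-square periodogram, tau estimation, actograms."""

import numpy as np
import pytest

import somnotype as st
from somnotype.rhythm import _qp
from _oracles import qp_bruteforce


def square_wave(period_bins, n_bins, high=80.0, duty=0.5):
    phase = np.arange(n_bins) % period_bins
    return np.where(phase < duty * period_bins, high, 0.0)


class TestQpStatistic:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = rng.random(rng.integers(40, 200))
            p = int(rng.integers(2, 20))
            assert _qp(s, p) == pytest.approx(qp_bruteforce(list(s), p))

    def test_pure_24h_square_wave_peaks_at_24h(self):
        series = square_wave(24, 28 * 24)  # hourly bins, 28 days
        pg = st.chi_square_periodogram(series, (16, 120), analysis_bin_s=3600)
        assert pg.periods_h[np.argmax(pg.qp)] == 24.0

    def test_constant_series_has_zero_qp(self):
        pg = st.chi_square_periodogram(
            np.full(2000, 7.0), (20, 28), analysis_bin_s=360
        )
        assert np.all(pg.qp == 0.0)

    def test_affine_rescaling_leaves_qp_unchanged(self):
        rng = np.random.default_rng(12)
        s = rng.random(1500)
        pg1 = st.chi_square_periodogram(s, (20, 28), analysis_bin_s=360)
        pg2 = st.chi_square_periodogram(5.0 * s + 3.0, (20, 28), analysis_bin_s=360)
        np.testing.assert_allclose(pg1.qp, pg2.qp, rtol=1e-9)

    def test_threshold_strictly_increases_with_df(self):
        pg = st.chi_square_periodogram(
            np.random.default_rng(1).random(2000), (20, 28), analysis_bin_s=360
        )
        assert np.all(np.diff(pg.threshold) > 0)

    def test_kfold_repetition_preserves_argmax_period(self):
        rng = np.random.default_rng(3)
        base = square_wave(25, 25 * 8) + rng.random(200)
        s3 = np.tile(base, 3)
        pg1 = st.chi_square_periodogram(base, (20, 28), analysis_bin_s=3600)
        pg3 = st.chi_square_periodogram(s3, (20, 28), analysis_bin_s=3600)
        assert (
            pg1.periods_h[np.argmax(pg1.qp)] == pg3.periods_h[np.argmax(pg3.qp)]
        )

    def test_period_range_beyond_half_series_rejected(self):
        with pytest.raises(st.ParameterError):
            st.chi_square_periodogram(np.ones(100), (20, 80), analysis_bin_s=3600)


class TestTauEstimation:
    def test_significant_peak_returned(self):
        series = square_wave(24, 24 * 12)
        pg = st.chi_square_periodogram(series, (16, 30), analysis_bin_s=3600)
        assert st.estimate_tau(pg) == 24.0

    def test_harmonic_outside_range_not_selected(self):
        # 24 h fundamental with a 12 h harmonic; search restricted to (20, 28)
        t = np.arange(24 * 20)
        series = 2 + np.cos(2 * np.pi * t / 24) + 0.8 * np.cos(2 * np.pi * t / 12)
        pg = st.chi_square_periodogram(series, (20, 28), analysis_bin_s=3600)
        assert st.estimate_tau(pg) == 24.0

    def test_arrhythmic_noise_returns_none_usually(self):
        rng = np.random.default_rng(0)
        hits = sum(
            st.estimate_tau(
                st.chi_square_periodogram(
                    rng.standard_normal(2000), (20, 28), analysis_bin_s=360
                )
            )
            is not None
            for _ in range(40)
        )
        assert hits <= 10  # per-period alpha, 81 correlated periods: mostly none

    def test_tie_breaks_toward_shorter_period(self):
        pg = st.Periodogram(
            periods_h=np.array([23.0, 24.0, 25.0]),
            qp=np.array([50.0, 50.0, 40.0]),
            df=np.array([229, 239, 249]),
            threshold=np.array([10.0, 10.0, 10.0]),
            alpha=0.01,
            bin_seconds=360,
        )
        assert st.estimate_tau(pg) == 23.0

    def test_search_range_outside_grid_rejected(self):
        pg = st.chi_square_periodogram(
            np.random.default_rng(2).random(2000), (20, 28), analysis_bin_s=360
        )
        with pytest.raises(st.ParameterError):
            st.estimate_tau(pg, search_range_h=(50, 60))


class TestActogram:
    def test_three_day_layout_with_padded_last_row(self):
        series = np.arange(72.0)  # 3 days, hourly
        mat = st.double_plot_actogram(series, bins_per_day=24)
        assert mat.shape == (3, 48)
        # row i right half == row i+1 left half (each day plotted twice)
        np.testing.assert_allclose(mat[0, 24:], mat[1, :24])
        assert np.isnan(mat[-1, 24:]).all()
        assert np.nanmax(mat) == 1.0

    def test_free_run_is_vertical_at_true_tau(self):
        # activity locked to a 25 h cycle: column variance across rows is
        # minimal when plotted modulo tau rather than modulo 24 h
        tau_bins, n_days = 25, 10
        series = np.tile(square_wave(tau_bins, tau_bins), n_days)
        mat_tau = st.double_plot_actogram(series, bins_per_day=tau_bins)
        mat_24 = st.double_plot_actogram(series[: n_days * 24], bins_per_day=24)
        var_tau = np.nanmean(np.nanvar(mat_tau, axis=0))
        var_24 = np.nanmean(np.nanvar(mat_24, axis=0))
        assert var_tau < var_24

    def test_empty_series_rejected(self):
        with pytest.raises(st.ParameterError):
            st.double_plot_actogram(np.array([]), 24)


class TestTauAdjustedActivity:
    @pytest.mark.parametrize("tau,expected", [(24.0, 10.0), (25.0, 9.6), (12.0, 20.0)])
    def test_adjustment_arithmetic(self, tau, expected):
        values = np.full(8640, 10.0)  # one day at 10% per bin
        adjusted, flag = st.tau_adjusted_daily_activity(values, tau, 10)
        assert flag
        assert adjusted == pytest.approx(24.0 / tau * 10.0 * 8640)

    def test_missing_tau_propagates_unadjusted(self):
        adjusted, flag = st.tau_adjusted_daily_activity(np.full(8640, 10.0), None, 10)
        assert not flag
        assert adjusted == pytest.approx(10.0 * 8640)


class TestLightResponseTable:
    def test_short_block_excluded_with_warning(self):
        blocks = (
            st.LightBlock(0, 5 * 86400, "DD", 0.0),
        )
        spec = st.MouseCohortSpec(n_per_genotype=1, days=5, seed=1)
        traces = st.simulate_mouse_activity(spec, st.LightingSchedule(blocks))
        with pytest.warns(UserWarning, match="excluded"):
            table = st.light_response_table(traces)
        assert table.empty

    def test_dd_tau_matches_intrinsic_period(self):
        spec = st.MouseCohortSpec(
            n_per_genotype=2, days=12,
            genotypes={"WT": st.GenotypeParams(intrinsic_tau_h=23.6,
                                               aschoff_slope=0.0)},
            seed=21,
        )
        traces = st.simulate_mouse_activity(spec, st.dd_schedule(12))
        table = st.light_response_table(traces)
        assert len(table) == 2
        assert np.allclose(table["tau_h"], 23.6, atol=0.1 + 1e-9)
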