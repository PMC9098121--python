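"""Smoothing splines, wave calling and elongation-rate fits."""

import numpy as np
import pytest

from conftest import make_toy_gene, uniform_track
from ttquant.synthetic_data import (
    SyntheticConfig,
    make_wave_gene_set,
    simulate_drb_wave_tracks,
    simulate_fp_clearance_tracks,
)
from ttquant.profiles import tss_reference_profile
from ttquant.wavefront import (
    SmoothCurve,
    WaveSeries,
    call_drb_wave_positions,
    fit_elongation_rate,
    fit_smooth_curve,
    fp_half_height_position,
    fp_half_height_series,
    fp_rear_slope,
    mean_rate_one_decimal,
    round_half_up,
)


class TestSmoothCurve:
    def test_interpolation_limit_reproduces_cubic(self):
        x = np.linspace(0, 10, 200)
        y = 0.5 * x**3 - 2 * x**2 + x + 3
        c = fit_smooth_curve(x, y, lam=1e-12)
        assert np.max(np.abs(c.values - y)) < 1e-6 * np.max(np.abs(y))

    def test_heavy_penalty_approaches_least_squares_line(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 150)
        y = 2 * x + 1 + rng.normal(0, 0.1, x.size)
        c = fit_smooth_curve(x, y, lam=1e9)
        coef = np.polyfit(x, y, 1)
        line = np.polyval(coef, x)
        assert np.max(np.abs(c.values - line)) < 0.01 * np.ptp(line)

    def test_noisy_edge_recovery(self):
        """GCV-smoothed fit of a noisy Gaussian-CDF edge stays within 5% of
        the amplitude of the truth."""
        from scipy.stats import norm

        rng = np.random.default_rng(6)
        x = np.linspace(0, 100, 1000)
        truth = 10 * norm.cdf((40 - x) / 5)
        y = rng.poisson(truth * 10) / 10
        c = fit_smooth_curve(x, y)
        assert np.max(np.abs(c.values - truth)) < 0.05 * 10

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_smooth_curve(np.arange(5.0), np.arange(5.0))


class TestDrbCalling:
    def _curves(self, positions, peaks_at, sd=2.0):
        from scipy.stats import norm

        out = {}
        for t, mu in peaks_at.items():
            y = np.exp(-0.5 * ((positions - mu) / sd) ** 2)
            out[t] = fit_smooth_curve(positions, y, lam=1e-10)
        return out

    def test_noiseless_waves_recover_true_fronts(self):
        x = np.linspace(0, 100, 1001)
        curves = self._curves(x, {0: 0.0, 10: 20.0, 20: 40.0, 30: 60.0, 40: 80.0})
        ws = call_drb_wave_positions(curves)
        assert np.allclose(ws.positions_kb, [0, 20, 40, 60, 80], atol=0.2)
        assert fit_elongation_rate(ws).rate == pytest.approx(2.0, abs=0.01)

    def test_monotone_constraint_flags_backwards_peak(self):
        x = np.linspace(0, 100, 1001)
        # the t=30 peak sits behind the t=20 one
        curves = self._curves(x, {10: 20.0, 20: 40.0, 30: 30.0})
        ws = call_drb_wave_positions(curves)
        assert np.all(np.diff(ws.positions_kb) >= 0)
        assert ws.constrained[2]
        assert ws.positions_kb[2] >= ws.positions_kb[1]

    def test_single_timepoint_gives_length_one_series(self):
        x = np.linspace(0, 100, 1001)
        curves = self._curves(x, {10: 20.0})
        ws = call_drb_wave_positions(curves)
        assert len(ws.times) == 1
        with pytest.raises(ValueError, match=">= 2"):
            fit_elongation_rate(ws)


class TestRateFit:
    def test_exact_line(self):
        ws = WaveSeries(times=[0, 10, 20, 30, 40], positions_kb=[0, 20, 40, 60, 80],
                        method="drb_peak")
        fit = fit_elongation_rate(ws)
        assert fit.rate == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(13)
        t = np.array([0.0, 10, 20, 30, 40])
        y = np.sort(rng.uniform(0, 100, 5))
        fit = fit_elongation_rate(WaveSeries(times=t, positions_kb=y, method="x"))
        slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert fit.rate == pytest.approx(slope, abs=1e-10)

    def test_position_offset_changes_intercept_not_rate(self):
        t = np.array([0.0, 10, 20])
        y = np.array([0.0, 21, 39])
        f1 = fit_elongation_rate(WaveSeries(times=t, positions_kb=y, method="x"))
        f2 = fit_elongation_rate(WaveSeries(times=t, positions_kb=y + 7, method="x"))
        assert f1.rate == pytest.approx(f2.rate)
        assert f2.intercept - f1.intercept == pytest.approx(7.0)

    def test_duplicate_times_error(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WaveSeries(times=[0, 0, 10], positions_kb=[0, 1, 2], method="x")


class TestFpRearSlope:
    def test_logistic_inflection_slope(self):
        """For L/(1+exp(-k(x-x0))), the inflection is at x0 with slope Lk/4."""
        L, k, x0 = 10.0, 0.8, 30.0
        x = np.linspace(0, 100, 2000)
        y = L / (1 + np.exp(-k * (x - x0)))
        c = fit_smooth_curve(x, y, lam=1e-10)
        slope = fp_rear_slope(c, min_kb=5.0)
        assert slope == pytest.approx(L * k / 4, rel=0.02)

    def test_pure_line_has_no_inflection(self):
        x = np.linspace(0, 100, 500)
        c = fit_smooth_curve(x, 2 * x + 1, lam=1e-10)
        with pytest.raises(ValueError, match="no inflection"):
            fp_rear_slope(c, min_kb=1.0, max_kb=99.0)

    def test_higher_speed_gives_shallower_rear_slope(self):
        cfg_slow = SyntheticConfig(seed=14, wave_speed=1.0, noise=False)
        cfg_fast = SyntheticConfig(seed=14, wave_speed=3.0, noise=False)
        slopes = {}
        for name, cfg in [("slow", cfg_slow), ("fast", cfg_fast)]:
            genes, lengths = make_wave_gene_set(cfg, n_genes=1)
            tracks, _ = simulate_fp_clearance_tracks(genes, lengths, cfg, [20])
            prof = tss_reference_profile(tracks[20], genes, downstream=200_000,
                                         upstream=0, bin_size=100, trim=0.0)
            kb = (prof.positions + 50) / 1e3
            c = fit_smooth_curve(kb, prof.means)
            slopes[name] = abs(fp_rear_slope(c, min_kb=2.0))
        assert slopes["fast"] < slopes["slow"]


class TestFpHalfHeight:
    def test_step_edge_position(self):
        gene = make_toy_gene("G", start=0, width=220_000)
        track = uniform_track(length=240_000, depth=0.0)
        track.data[("chrT", "+")][30_000:220_000] = 10.0
        pos = fp_half_height_position(track, gene)
        assert pos == pytest.approx(30.0, abs=0.1)

    def test_gaussian_cdf_edge_centre(self):
        from scipy.stats import norm

        gene = make_toy_gene("G", start=0, width=220_000)
        track = uniform_track(length=240_000, depth=0.0)
        x = np.arange(240_000)
        track.data[("chrT", "+")][:220_000] = 10 * norm.cdf((x[:220_000] - 30_000) / 2000)
        pos = fp_half_height_position(track, gene)
        assert pos == pytest.approx(30.0, abs=0.05)

    def test_never_half_max_excluded(self):
        gene = make_toy_gene("G", start=0, width=220_000)
        track = uniform_track(length=240_000, depth=0.0)
        # rises but never above 0.25 of its max within the window after the dip
        track.data[("chrT", "+")][:220_000] = np.linspace(10, 0, 220_000)
        # monotone decreasing: max at TSS, last below-quartile point near the
        # end, no upward crossing after it
        assert fp_half_height_position(track, gene) is None


class TestRecovery:
    @pytest.mark.parametrize("v", [1.0, 3.4])
    def test_fp_per_gene_rates_within_ten_percent(self, v):
        cfg = SyntheticConfig(seed=17, wave_speed=v)
        genes, lengths = make_wave_gene_set(cfg, n_genes=3)
        tps = [5, 10, 15, 20, 25] if v > 2 else [10, 20, 30, 40, 50]
        tracks, _ = simulate_fp_clearance_tracks(genes, lengths, cfg, tps)
        rates = []
        for g in genes:
            fit = fit_elongation_rate(fp_half_height_series(tracks, g))
            assert abs(fit.rate - v) / v < 0.10
            rates.append(fit.rate)
        assert abs(mean_rate_one_decimal(rates) - v) <= 0.2

    def test_drb_metaprofile_rate_within_ten_percent(self):
        v = 2.1
        cfg = SyntheticConfig(seed=18, wave_speed=v)
        genes, lengths = make_wave_gene_set(cfg, n_genes=3)
        tracks, _ = simulate_drb_wave_tracks(genes, lengths, cfg, [0, 10, 20, 30, 40])
        curves = {}
        for t, tr in tracks.items():
            prof = tss_reference_profile(tr, genes, downstream=200_000, upstream=2000,
                                         bin_size=100, trim=0.0)
            kb = (prof.positions + 50) / 1e3
            curves[t] = fit_smooth_curve(kb, prof.means)
        fit = fit_elongation_rate(call_drb_wave_positions(curves))
        assert abs(fit.rate - v) / v < 0.10


class TestReporting:
    def test_round_half_up(self):
        assert round_half_up(2.55, 1) == 2.6
        assert round_half_up(2.25, 1) == 2.3   # ties away from zero
        assert round_half_up(3.44, 1) == 3.4

    def test_mean_rate_one_decimal(self):
        assert mean_rate_one_decimal([2.09, 2.76, 2.8]) == 2.6
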