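"""Photobleaching correction, center fraction, and the two-sided I_Ratio estimator."""

import numpy as np
import pytest

from minwave.profile_analysis import (
    ProfileSeries,
    biexp_snapshot_correction,
    center_fraction,
    estimate_iratio_experimental,
    molecules_from_intensity,
    photobleach_normalize,
)
from minwave.synthetic_data import SyntheticSpec, make_profile_series, make_snapshot_series


def uniform_series(length_um=2.0, n_frames=5, n_x=51, value=1.0):
    return ProfileSeries(
        times=np.arange(n_frames, dtype=float),
        positions=np.linspace(0, 1, n_x),
        intensities=np.full((n_frames, n_x), value),
        length_um=length_um,
    )


class TestPhotobleachNormalize:
    def test_constant_totals_left_unchanged_beyond_min_shift(self):
        spec = SyntheticSpec(a=1.0, lambda_=2.0, c=0.3, period=10.0,
                             n_frames=32, frame_interval=1.0)
        series, _ = make_profile_series(spec)
        corrected = photobleach_normalize(series)
        assert abs(corrected.bleach_rate) < 1e-9
        shifted = series.intensities - series.intensities.min(axis=1, keepdims=True)
        np.testing.assert_allclose(corrected.intensities, shifted, rtol=1e-9)

    def test_recovers_synthetic_bleach_rate(self):
        spec = SyntheticSpec(a=1.0, lambda_=2.0, c=0.0, period=10.0, n_frames=64,
                             frame_interval=1.0, bleach_rate=0.01)
        series, truth = make_profile_series(spec)
        corrected = photobleach_normalize(series)
        assert 0.009 <= corrected.bleach_rate <= 0.011
        totals = corrected.intensities.sum(axis=1)
        assert totals.std() / totals.mean() < 0.01

    def test_trend_reduction_factor(self):
        spec = SyntheticSpec(a=1.0, lambda_=2.0, c=0.0, period=10.0, n_frames=64,
                             frame_interval=1.0, bleach_rate=0.02)
        series, _ = make_profile_series(spec)
        corrected = photobleach_normalize(series)
        slope_in = abs(np.polyfit(series.times, series.totals, 1)[0])
        slope_out = abs(np.polyfit(corrected.times, corrected.totals, 1)[0])
        assert slope_in / max(slope_out, 1e-300) >= 100.0

    def test_reapplying_fitted_decay_restores_input(self):
        spec = SyntheticSpec(a=1.0, lambda_=2.0, c=0.0, period=10.0, n_frames=48,
                             frame_interval=1.0, bleach_rate=0.015)
        series, _ = make_profile_series(spec)
        corrected = photobleach_normalize(series)
        shifted = series.intensities - series.intensities.min(axis=1, keepdims=True)
        restored = corrected.intensities * np.exp(-corrected.bleach_rate * series.times)[:, None]
        np.testing.assert_allclose(restored, shifted, atol=1e-8)

    def test_requires_three_frames(self):
        with pytest.raises(ValueError):
            photobleach_normalize(uniform_series(n_frames=2))


class TestCenterFraction:
    def test_uniform_profile_covers_zone_fraction(self):
        # +/-100 nm on a 2-um cell is 10% of the normalized length
        assert center_fraction(uniform_series(length_um=2.0)) == pytest.approx(0.1, abs=1e-12)

    def test_matches_dense_quadrature_oracle_on_piecewise_linear(self, rng):
        x = np.linspace(0, 1, 41)
        for _ in range(10):
            knots = np.sort(rng.uniform(0, 1, 6))
            vals = rng.uniform(0.1, 2.0, 6)
            profile = np.interp(x, knots, vals)
            series = ProfileSeries(np.arange(3.0), x, np.tile(profile, (3, 1)), 2.0)
            got = center_fraction(series)
            xx = np.linspace(0, 1, 200001)
            dense = np.interp(xx, x, profile)
            zone = (xx >= 0.45) & (xx <= 0.55)
            want = np.trapezoid(dense[zone], xx[zone]) / np.trapezoid(dense, xx)
            assert got == pytest.approx(want, abs=1e-4)

    def test_midcell_depleted_profile_below_uniform(self):
        x = np.linspace(0, 1, 51)
        v_shape = 0.2 + np.abs(x - 0.5)  # MinD-gradient-like midcell dip
        series = ProfileSeries(np.arange(3.0), x, np.tile(v_shape, (3, 1)), 2.0)
        assert center_fraction(series) < 0.1

    def test_short_cell_rejected(self):
        with pytest.raises(ValueError):
            center_fraction(uniform_series(length_um=0.15))


class TestEstimateIRatio:
    def test_clean_alternating_gradients_give_closed_form(self):
        # d e^(-2|x|) vs d e^(-2|x-1|): intersection at 0.5, ratio e^-1
        spec = SyntheticSpec(a=1.0, lambda_=2.0, c=0.0, period=10.0,
                             n_frames=64, frame_interval=1.0)
        series, truth = make_profile_series(spec)
        fit = estimate_iratio_experimental(series)
        assert fit.i_ratio == pytest.approx(np.exp(-1.0), abs=1e-3)
        assert fit.m_left == pytest.approx(0.0, abs=1e-9)
        assert fit.m_right == pytest.approx(1.0, abs=1e-9)

    def test_shared_decay_is_size_weighted_mean(self):
        # printed-form arithmetic: (2*10 + 4*30) / 40 = 3.5
        lam = (2.0 * 10 + 4.0 * 30) / (10 + 30)
        assert lam == 3.5

    def test_scale_invariance(self):
        spec = SyntheticSpec(a=1.0, lambda_=2.0, c=0.0, period=10.0,
                             n_frames=64, frame_interval=1.0, noise_sd=0.005)
        series, _ = make_profile_series(spec)
        fit1 = estimate_iratio_experimental(series)
        scaled = ProfileSeries(series.times, series.positions,
                               123.4 * series.intensities, series.length_um)
        fit2 = estimate_iratio_experimental(scaled)
        assert fit2.i_ratio == pytest.approx(fit1.i_ratio, rel=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        # ground truth I_Ratio = 0.45 (lambda = 2 ln(1/0.45), c = 0)
        lam = 2.0 * np.log(1.0 / 0.45)
        errs = []
        for seed in range(50):
            spec = SyntheticSpec(a=1.0, lambda_=lam, c=0.0, period=10.0, n_frames=64,
                                 frame_interval=1.0, noise_sd=0.01, seed=seed)
            series, truth = make_profile_series(spec)
            fit = estimate_iratio_experimental(series)
            errs.append(fit.i_ratio - truth["i_ratio"])
        assert np.max(np.abs(errs)) < 0.05

    def test_one_sided_series_rejected(self):
        x = np.linspace(0, 1, 51)
        g = np.exp(-2.0 * x)
        series = ProfileSeries(np.arange(10.0), x, np.tile(g, (10, 1)), 3.0)
        with pytest.raises(ValueError):
            estimate_iratio_experimental(series)


class TestBiexpCorrection:
    def test_recovers_generator_parameters(self):
        snap, truth = make_snapshot_series(SyntheticSpec(seed=4), n_rounds=50, growth_slope=0.0)
        fit = biexp_snapshot_correction(snap)
        a1, b1, a2, b2 = truth["biexp"]
        assert fit.a1 == pytest.approx(a1, rel=0.05)
        assert fit.b1 == pytest.approx(b1, rel=0.05)
        assert fit.a2 == pytest.approx(a2, rel=0.05)
        assert fit.b2 == pytest.approx(b2, rel=0.05)

    def test_flat_cells_corrected_flat(self):
        snap, _ = make_snapshot_series(SyntheticSpec(seed=5), growth_slope=0.0)
        fit = biexp_snapshot_correction(snap)
        rel_spread = fit.corrected.std(axis=1) / fit.corrected.mean(axis=1)
        assert np.all(rel_spread < 1e-6)
        assert abs(fit.alpha_mean) < 1e-6 * fit.beta_mean

    def test_growth_slope_recovered_and_linear(self):
        snap, truth = make_snapshot_series(SyntheticSpec(seed=6), growth_slope=0.5)
        fit = biexp_snapshot_correction(snap)
        assert fit.alpha_mean == pytest.approx(truth["growth_slope"], rel=0.02)
        snap2, truth2 = make_snapshot_series(SyntheticSpec(seed=6), growth_slope=1.0)
        fit2 = biexp_snapshot_correction(snap2)
        assert fit2.alpha_mean == pytest.approx(2.0 * fit.alpha_mean, rel=0.02)


class TestMoleculesFromIntensity:
    def test_anchor_pins_conversion(self):
        # intensity line anchored to 2205 molecules at t = 75 min
        out = molecules_from_intensity(
            fit_slope=2.0, fit_intercept=100.0, anchor_time=75.0,
            anchor_molecules=2205.0, times=np.array([0.0, 75.0, 90.0]),
        )
        assert out["conversion_factor"] == pytest.approx(2205.0 / 250.0)
        assert out["molecules"][1] == pytest.approx(2205.0)

    def test_zone_counts_scale_with_center_fraction(self):
        out = molecules_from_intensity(
            fit_slope=0.0, fit_intercept=50.0, anchor_time=10.0,
            anchor_molecules=2000.0, times=np.array([10.0]), center_frac=0.1,
        )
        assert out["midzone_molecules"][0] == pytest.approx(200.0)

    def test_linear_count_series_recovered_from_noisy_fit(self, rng):
        t = np.linspace(0, 90, 50)
        intensity = 1800 + 8.0 * t + rng.normal(0, 20, t.size)
        slope, intercept = np.polyfit(t, intensity, 1)
        out = molecules_from_intensity(
            fit_slope=slope, fit_intercept=intercept, anchor_time=45.0,
            anchor_molecules=float(slope * 45 + intercept), times=np.array([0.0, 90.0]),
        )
        assert out["molecules"][0] == pytest.approx(1800.0, rel=0.03)
        assert out["molecules"][1] == pytest.approx(1800 + 8 * 90, rel=0.03)

    def test_anchor_outside_range_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            molecules_from_intensity(
                fit_slope=1.0, fit_intercept=1.0, anchor_time=100.0,
                anchor_molecules=10.0, times=np.array([0.0]),
                fitted_range=(0.0, 90.0),
            )
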