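"""Anisotropy computation, confidence intervals, G calibration and fitting."""

import numpy as np
import pytest

from starss.analysis import (
    AnisotropyCurve,
    analyze_method3,
    build_method3_calibration,
    calibrate_g,
    compute_anisotropy,
    confidence_interval_95,
    fit_monoexponential,
    fit_stretched,
)
from starss.photophysics import RotorModel
from starss.schemes import DecayCurve, ModulationCurve, simulate_method3, substream


def make_curve(par, perp, widths=1.0, labels="probe", meta=None):
    par = np.asarray(par, dtype=float)
    n = len(par)
    t = np.arange(n, dtype=float) + 0.5
    return DecayCurve(
        t, par, np.asarray(perp, dtype=float),
        np.broadcast_to(np.asarray(widths, dtype=float), (n,)).copy(),
        np.asarray([labels] * n, dtype=object), meta or {"mode": "poisson"},
    )


def synthetic_aniso(t, r, sigma=None, meta=None):
    s = np.full_like(t, 1e-4 if sigma is None else 0.0) if sigma is None else sigma
    lo = r - 1.96 * s
    hi = r + 1.96 * s
    return AnisotropyCurve(t, r, lo, hi, np.ones_like(t, dtype=bool),
                           metadata=meta or {"mode": "expectation"})


class TestComputeAnisotropy:
    @pytest.mark.parametrize(
        "ipar,iperp,G,bg,expected",
        [
            (100.0, 100.0, 1.0, 0.0, 0.0),
            (300.0, 100.0, 1.0, 0.0, 0.4),
            (120.0, 60.0, 2.0, 20.0, (100 - 80) / (100 + 160)),
        ],
    )
    def test_formula_arithmetic(self, ipar, iperp, G, bg, expected):
        curve = make_curve([ipar] * 3, [iperp] * 3)
        a = compute_anisotropy(curve, G=G, background=(bg, bg))
        np.testing.assert_allclose(a.r, expected, atol=1e-12)

    def test_invalid_bins_flagged_not_dropped(self):
        curve = make_curve([100, 5, 100], [50, 5, 50])
        a = compute_anisotropy(curve, background=(10.0, 10.0))  # bin 1 goes negative
        assert len(a.r) == 3
        assert a.valid[0] and a.valid[2] and not a.valid[1]
        assert np.isnan(a.r[1])

    def test_rejects_bad_inputs(self):
        curve = make_curve([1.0], [1.0])
        with pytest.raises(ValueError):
            compute_anisotropy(curve, G=0.0)
        with pytest.raises(ValueError):
            compute_anisotropy(curve, background=(-1.0, 0.0))

    def test_gain_invariance(self):
        """Scaling the perpendicular channel and G together leaves r unchanged."""
        rng = np.random.default_rng(0)
        par = rng.poisson(500, 20).astype(float)
        perp = rng.poisson(300, 20).astype(float)
        a1 = compute_anisotropy(make_curve(par, perp), G=1.0)
        # a gain change on the perpendicular channel rescales the calibrated
        # G inversely, leaving r unchanged
        c = 2.7
        a2 = compute_anisotropy(make_curve(par, perp * c), G=1.0 / c)
        np.testing.assert_allclose(a1.r, a2.r, rtol=1e-12)

    def test_background_subtraction_round_trip(self):
        par = np.full(10, 400.0)
        perp = np.full(10, 200.0)
        r_clean = compute_anisotropy(make_curve(par, perp)).r
        b = 120.0
        r_corrected = compute_anisotropy(
            make_curve(par + b, perp + b), background=(b, b)
        ).r
        np.testing.assert_allclose(r_corrected, r_clean, rtol=1e-12)


class TestConfidenceIntervals:
    def test_width_shrinks_with_root_n(self):
        lo1, hi1 = confidence_interval_95(300.0, 100.0)
        lo2, hi2 = confidence_interval_95(30000.0, 10000.0)
        assert (hi2 - lo2) == pytest.approx((hi1 - lo1) / 10.0, rel=1e-6)

    def test_symmetric_channels_bracket_zero(self):
        lo, hi = confidence_interval_95(500.0, 500.0)
        assert lo < 0 < hi
        assert np.isclose(-lo, hi, rtol=1e-9)

    def test_delta_matches_bootstrap(self):
        lo_d, hi_d = confidence_interval_95(300.0, 100.0, method="delta")
        lo_b, hi_b = confidence_interval_95(300.0, 100.0, method="bootstrap",
                                            n_boot=4000, seed=1)
        assert (hi_b - lo_b) == pytest.approx(hi_d - lo_d, rel=0.15)

    def test_zero_counts_undefined(self):
        lo, hi = confidence_interval_95(0.0, 0.0)
        assert np.isnan(lo) and np.isnan(hi)


class TestCalibrateG:
    def test_plain_gain_ratio(self):
        assert calibrate_g(make_curve([200.0] * 10, [100.0] * 10)) == pytest.approx(2.0)
        assert calibrate_g(make_curve([100.0] * 10, [100.0] * 10)) == pytest.approx(1.0)

    def test_poisson_record_recovers_g_within_one_percent(self):
        rng = substream(5, "gcal")
        n_bins, per_bin = 100, 1e4  # one million counts total
        par = rng.poisson(1.3 * per_bin, n_bins)
        perp = rng.poisson(per_bin, n_bins)
        assert calibrate_g(make_curve(par, perp)) == pytest.approx(1.3, rel=0.01)

    def test_time_trend_warns(self):
        t = np.arange(50)
        par = 1000.0 + 20.0 * t
        perp = np.full(50, 1000.0)
        with pytest.warns(UserWarning, match="trend"):
            calibrate_g(make_curve(par, perp))

    def test_calibrated_record_reads_zero_anisotropy(self):
        rng = substream(6, "gcal2")
        par = rng.poisson(2.0 * 5e3, 200).astype(float)
        perp = rng.poisson(5e3, 200).astype(float)
        curve = make_curve(par, perp)
        G = calibrate_g(curve)
        a = compute_anisotropy(curve, G=G)
        mean_r = np.nanmean(a.r)
        assert abs(mean_r) < np.nanmean(a.sigma)  # zero within noise


class TestMonoexponentialFit:
    def test_noiseless_generative_recovery(self):
        t = np.linspace(1e-6, 400e-6, 200)
        r = 0.05 + 0.25 * np.exp(-t / 50e-6)
        fit = fit_monoexponential(synthetic_aniso(t, r))
        assert fit.tau == pytest.approx(50e-6, rel=1e-6)
        assert fit.r_static == pytest.approx(0.05, abs=1e-8)
        assert fit.amplitude == pytest.approx(0.25, abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_poisson_noise_recovery_within_10_percent(self, seed):
        t = np.linspace(1e-6, 400e-6, 200)
        r_true = 0.05 + 0.25 * np.exp(-t / 50e-6)
        S = 1e6 / len(t)  # one million photons split over the bins
        rng = substream(seed, "fit")
        par = rng.poisson(S * (1 + 2 * r_true) / 3)
        perp = rng.poisson(S * (1 - r_true) / 3)
        curve = DecayCurve(t, par, perp, np.full_like(t, t[1] - t[0]),
                           np.asarray(["probe"] * len(t), dtype=object),
                           {"mode": "poisson"})
        fit = fit_monoexponential(compute_anisotropy(curve))
        assert fit.tau == pytest.approx(50e-6, rel=0.10)

    def test_flat_curve_flags_tau_unconstrained(self):
        t = np.linspace(1e-6, 400e-6, 100)
        fit = fit_monoexponential(synthetic_aniso(t, np.full_like(t, 0.3)))
        assert fit.tau_unconstrained
        assert fit.r_static == pytest.approx(0.3, abs=1e-9)
        assert np.isnan(fit.tau)

    def test_diameter_ci_propagates_cube_root(self):
        t = np.linspace(1e-6, 400e-6, 200)
        r_true = 0.05 + 0.25 * np.exp(-t / 50e-6)
        S = 5e5
        rng = substream(9, "fitci")
        par = rng.poisson(S * (1 + 2 * r_true) / 3)
        perp = rng.poisson(S * (1 - r_true) / 3)
        curve = DecayCurve(t, par, perp, np.full_like(t, t[1] - t[0]),
                           np.asarray(["probe"] * len(t), dtype=object),
                           {"mode": "poisson"})
        fit = fit_monoexponential(compute_anisotropy(curve))
        lo, hi = fit.diameter_ci95
        assert lo < fit.diameter < hi
        # interval endpoints are the cube-root images of the tau endpoints
        from starss.sizes import diameter_from_tau

        assert lo == pytest.approx(diameter_from_tau(fit.tau_ci95[0]), rel=1e-9)

    def test_too_few_bins_rejected(self):
        t = np.linspace(1e-6, 10e-6, 5)
        with pytest.raises(ValueError, match="8 valid bins"):
            fit_monoexponential(synthetic_aniso(t, np.exp(-t / 3e-6)))


class TestStretchedFit:
    def test_noiseless_beta_half_recovery(self):
        t = np.linspace(1e-6, 400e-6, 300)
        r = 0.02 + 0.3 * np.exp(-np.power(t / 30e-6, 0.5))
        fit = fit_stretched(synthetic_aniso(t, r))
        assert fit.beta == pytest.approx(0.5, abs=1e-4)
        assert fit.tau == pytest.approx(30e-6, rel=1e-3)

    def test_nested_model_prefers_monoexp_when_beta_is_one(self):
        t = np.linspace(1e-6, 400e-6, 200)
        r = 0.05 + 0.25 * np.exp(-t / 50e-6)
        aniso = synthetic_aniso(t, r)
        mono = fit_monoexponential(aniso)
        stretched = fit_stretched(aniso)
        assert stretched.beta == pytest.approx(1.0, abs=0.02)
        assert mono.aicc <= stretched.aicc + 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_noisy_beta_recovery_within_tenth(self, seed):
        t = np.linspace(1e-6, 400e-6, 200)
        r_true = 0.02 + 0.3 * np.exp(-np.power(t / 30e-6, 0.6))
        S = 1e7 / len(t)
        rng = substream(seed, "beta")
        par = rng.poisson(S * (1 + 2 * r_true) / 3)
        perp = rng.poisson(S * (1 - r_true) / 3)
        curve = DecayCurve(t, par, perp, np.full_like(t, t[1] - t[0]),
                           np.asarray(["probe"] * len(t), dtype=object),
                           {"mode": "poisson"})
        fit = fit_stretched(compute_anisotropy(curve))
        assert fit.beta == pytest.approx(0.6, abs=0.1)


class TestAnalyzeMethod3:
    @pytest.fixture(scope="class")
    def slow_mod(self, fluor, grid):
        from starss.photophysics import Illumination

        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=200.0, duration=60e-6)
        return simulate_method3(
            fluor, RotorModel(rotational_correlation_time=30e-6),
            delays=np.geomspace(0.5e-6, 500e-6, 7), probe_488=probe, grid=grid,
        ), probe

    def test_closed_loop_recovery_within_20_percent(self, fluor, grid, slow_mod):
        mod, probe = slow_mod
        cal = build_method3_calibration(
            fluor, [5e-6, 15e-6, 45e-6, 135e-6],
            delays=np.geomspace(0.5e-6, 500e-6, 7), grid=grid, probe_488=probe,
        )
        res = analyze_method3(mod, calibration=cal)
        assert res.tau_rot == pytest.approx(30e-6, rel=0.20)

    def test_static_sample_flagged_unconstrained(self, fluor, grid, slow_mod):
        _, probe = slow_mod
        mod = simulate_method3(fluor, RotorModel.static(),
                               delays=np.geomspace(0.5e-6, 500e-6, 5),
                               probe_488=probe, grid=grid)
        res = analyze_method3(mod)
        assert res.tau_unconstrained
        assert np.isnan(res.tau_rot)

    def test_fast_rotor_flagged_below_resolution(self):
        d = np.geomspace(1e-6, 500e-6, 8)
        y = 1.5 - 0.2 * np.exp(-d / 1e-7)  # already saturated at the first delay
        y[0] -= 1e-4  # tiny residual rise
        mod = ModulationCurve(d, y * 100, 100.0, metadata={"mode": "poisson"})
        res = analyze_method3(mod)
        assert res.below_resolution or res.tau_unconstrained

    def test_too_few_delays_rejected(self):
        mod = ModulationCurve(np.array([1e-6, 2e-6]), np.array([10.0, 11.0]), 10.0)
        with pytest.raises(ValueError, match="5 delays"):
            analyze_method3(mod)
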