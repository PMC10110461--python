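"""Forward simulation of the three pulse schemes and the detector model."""

import numpy as np
import pytest

from starss.analysis import compute_anisotropy, fit_monoexponential
from starss.photophysics import FluorophoreModel, Illumination, RotorModel
from starss.schemes import (
    DetectorPair,
    PulseScheme,
    SchemeSegment,
    estimate_background,
    simulate_method1,
    simulate_method2,
    simulate_method3,
    simulate_scheme,
    substream,
)

from conftest import poissonify


def total(curve):
    return curve.counts_parallel.sum() + curve.counts_perpendicular.sum()


class TestMethod1:
    def test_static_rotor_is_flat_near_ceiling(self, fluor, grid, circular_probe):
        curve = simulate_method1(fluor, RotorModel.static(), probe_488=circular_probe,
                                 grid=grid, mode="expectation", bin_width=2e-6)
        a = compute_anisotropy(curve)
        r = a.r[a.valid]
        assert np.nanmax(r) - np.nanmin(r) < 0.02  # flat reference sample
        assert np.nanmax(r) <= 0.4 + 1e-3          # photoselection ceiling

    def test_fast_rotor_reads_zero(self, fluor, grid):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=100.0, duration=100e-6)
        curve = simulate_method1(fluor, RotorModel(rotational_correlation_time=1e-9),
                                 probe_488=probe, grid=grid, mode="expectation",
                                 bin_width=2e-6)
        a = compute_anisotropy(curve)
        assert np.nanmax(np.abs(a.r[a.valid])) < 1e-6

    def test_noiseless_decay_time_matches_rotor(self, method1_slow_curve):
        """Free-rotor r(t) ~ exp(-t/tau_rot): fit recovers tau within 5%."""
        fit = fit_monoexponential(compute_anisotropy(method1_slow_curve))
        assert fit.tau == pytest.approx(50e-6, rel=0.05)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_poisson_recovery_within_15_percent(self, method1_slow_curve, seed):
        cycles = int(1e7 / total(method1_slow_curve))
        noisy = poissonify(method1_slow_curve, cycles, seed)
        fit = fit_monoexponential(compute_anisotropy(noisy))
        assert fit.tau == pytest.approx(50e-6, rel=0.15)

    def test_diameter_accepts_raw_meters(self, fluor, grid):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=100.0, duration=50e-6)
        curve = simulate_method1(fluor, 60e-9, probe_488=probe, grid=grid,
                                 mode="expectation", bin_width=2e-6)
        assert total(curve) > 0

    def test_undersampled_probe_warns(self, fluor, grid):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=2e6, duration=100e-6)
        with pytest.warns(UserWarning, match="undersampled"):
            simulate_method1(fluor, RotorModel.static(), probe_488=probe,
                             grid=grid, mode="expectation", bin_width=10e-6)

    def test_pulse_polarization_validated(self, fluor, grid):
        bad = Illumination(role="switch_on_405", polarization="circular",
                           power_density=1e4, duration=250e-9)
        with pytest.raises(ValueError, match="linear"):
            simulate_method1(fluor, RotorModel.static(), pulse_405=bad, grid=grid)


class TestMethod2:
    def test_fast_rotation_keeps_anisotropy_stationary(self, fluor, grid):
        curve = simulate_method2(fluor, RotorModel(rotational_correlation_time=0.1e-6),
                                 grid=grid, mode="expectation", bin_width=2e-6)
        a = compute_anisotropy(curve)
        r = a.r[a.valid]
        assert np.nanmax(np.abs(np.diff(r))) < 1e-6
        assert r[0] == pytest.approx(0.4, abs=0.01)  # steady-state photoselection

    def test_static_rotor_decays_monotonically(self, fluor, grid):
        curve = simulate_method2(fluor, RotorModel.static(), grid=grid,
                                 mode="expectation", bin_width=2e-6)
        a = compute_anisotropy(curve)
        r = a.r[a.valid]
        assert r[0] > r[-1]
        assert np.all(np.diff(r) < 1e-9)

    def test_parallel_channel_depletes_faster_when_static(self, fluor, grid):
        curve = simulate_method2(fluor, RotorModel.static(), grid=grid,
                                 mode="expectation", bin_width=2e-6)
        ratio = curve.counts_parallel / curve.counts_perpendicular
        assert ratio[0] > ratio[-1]

    def test_tenfold_yield_vs_method1_preset(self, fluor, grid):
        """100% ON initialization yields 10x the photons of the 10% preset."""
        rotor = RotorModel(rotational_correlation_time=5e-6)
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=1000.0, duration=5e-3)
        c1 = simulate_method1(fluor, rotor, probe_488=probe, grid=grid,
                              mode="expectation", bin_width=50e-6)
        scheme = PulseScheme((SchemeSegment(probe.duration, probe, detect=True,
                                            bin_width=50e-6, label="probe"),))
        c2 = simulate_scheme(scheme, fluor, rotor, grid=grid, mode="expectation",
                             initial_on_fraction=1.0)
        assert total(c2) / total(c1) == pytest.approx(10.0, rel=0.02)

    def test_probe_polarization_validated(self, fluor, grid):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=100.0, duration=1e-3)
        with pytest.raises(ValueError, match="linear"):
            simulate_method2(fluor, RotorModel.static(), probe_488=probe, grid=grid)


class TestMethod3:
    DELAYS = np.geomspace(0.5e-6, 500e-6, 5)

    def test_zero_second_pulse_normalizes_to_one(self, fluor, grid):
        """Without a second pulse the scheme degenerates to the reference."""
        second = Illumination(role="switch_on_405", polarization="linear",
                              power_density=0.0, duration=50e-9)
        mod = simulate_method3(fluor, RotorModel(rotational_correlation_time=30e-6),
                               delays=self.DELAYS, second_pulse=second, grid=grid)
        np.testing.assert_allclose(mod.normalized, 1.0, rtol=5e-3)

    def test_static_rotor_is_delay_independent(self, fluor, grid):
        mod = simulate_method3(fluor, RotorModel.static(), delays=self.DELAYS,
                               grid=grid)
        assert np.ptp(mod.normalized) < 1e-9

    def test_slow_rotor_counts_rise_with_delay(self, fluor, grid):
        mod = simulate_method3(fluor, RotorModel(rotational_correlation_time=30e-6),
                               delays=self.DELAYS, grid=grid)
        n = mod.normalized
        assert n[-1] > n[0]
        assert np.all(np.diff(n) > -1e-12)

    def test_delay_shorter_than_pulse_rejected(self, fluor, grid):
        with pytest.raises(ValueError, match="delays"):
            simulate_method3(fluor, RotorModel.static(), delays=[10e-9],
                             grid=grid, delay_range=(1e-9, 500e-6))

    def test_polarization_resolved_mode_keeps_channels(self, fluor, grid):
        mod = simulate_method3(fluor, RotorModel(rotational_correlation_time=30e-6),
                               delays=self.DELAYS[:5],
                               grid=grid, polarization_resolved=True)
        assert mod.counts_parallel is not None
        np.testing.assert_allclose(
            mod.counts_parallel + mod.counts_perpendicular, mod.total_counts
        )


class TestDetectorAndSampling:
    def test_seeded_runs_are_bit_identical(self, fluor, grid):
        kw = dict(probe_488=Illumination(role="probe_488", polarization="circular",
                                         power_density=100.0, duration=50e-6),
                  grid=grid, mode="poisson", bin_width=2e-6, cycles=2000, seed=7)
        rotor = RotorModel(rotational_correlation_time=20e-6)
        a = simulate_method1(fluor, rotor, **kw)
        b = simulate_method1(fluor, rotor, **kw)
        np.testing.assert_array_equal(a.counts_parallel, b.counts_parallel)
        np.testing.assert_array_equal(a.counts_perpendicular, b.counts_perpendicular)

    def test_sampled_counts_consistent_with_expectation(self, method1_slow_curve):
        """Poisson totals agree with the expectation within a few sigma."""
        cycles = 50000
        noisy = poissonify(method1_slow_curve, cycles, seed=11)
        exp_total = cycles * total(method1_slow_curve)
        assert abs(total(noisy) - exp_total) < 5 * np.sqrt(exp_total)

    def test_counts_scale_linearly_with_cycles_and_brightness(self, fluor, grid):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=100.0, duration=50e-6)
        rotor = RotorModel(rotational_correlation_time=20e-6)
        base = simulate_method1(fluor, rotor, probe_488=probe, grid=grid,
                                mode="expectation", bin_width=2e-6)
        doubled = simulate_method1(fluor, rotor, probe_488=probe, grid=grid,
                                   mode="expectation", bin_width=2e-6, cycles=2)
        assert total(doubled) == pytest.approx(2 * total(base), rel=1e-12)
        import dataclasses

        brighter = dataclasses.replace(fluor, brightness=2 * fluor.brightness)
        b2 = simulate_method1(brighter, rotor, probe_488=probe, grid=grid,
                              mode="expectation", bin_width=2e-6)
        assert total(b2) == pytest.approx(2 * total(base), rel=1e-10)

    def test_g_factor_scales_parallel_channel(self, fluor, grid):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=100.0, duration=50e-6)
        rotor = RotorModel(rotational_correlation_time=20e-6)
        det = DetectorPair(g_factor=2.0)
        c1 = simulate_method1(fluor, rotor, probe_488=probe, grid=grid,
                              mode="expectation", bin_width=2e-6)
        c2 = simulate_method1(fluor, rotor, detector=det, probe_488=probe, grid=grid,
                              mode="expectation", bin_width=2e-6)
        np.testing.assert_allclose(c2.counts_parallel, 2 * c1.counts_parallel)
        np.testing.assert_allclose(c2.counts_perpendicular, c1.counts_perpendicular)


class TestBackgroundEstimation:
    def make_curve_with_reset(self, fluor, grid, background_rate):
        probe = Illumination(role="probe_488", polarization="circular",
                             power_density=100.0, duration=50e-6)
        det = DetectorPair(background_rate=background_rate)
        return simulate_method1(fluor, RotorModel(rotational_correlation_time=20e-6),
                                detector=det, probe_488=probe, grid=grid,
                                mode="expectation", bin_width=2e-6, include_reset=True)

    def test_recovers_injected_background(self, fluor, grid):
        curve = self.make_curve_with_reset(fluor, grid, background_rate=5000.0)
        bpar, bperp = estimate_background(curve)
        assert bpar == pytest.approx(5000.0, rel=0.05)
        assert bperp == pytest.approx(5000.0, rel=0.05)

    def test_zero_background_estimates_zero(self, fluor, grid):
        curve = self.make_curve_with_reset(fluor, grid, background_rate=0.0)
        bpar, bperp = estimate_background(curve)
        # residual probe signal in the reset tail is << the probe count rate
        probe_rate = curve.select("probe").counts_parallel.sum() / 50e-6
        assert bpar < 1e-2 * probe_rate

    def test_missing_reset_window_errors(self, method1_slow_curve):
        with pytest.raises(ValueError, match="reset"):
            estimate_background(method1_slow_curve)

    def test_background_only_record_flags_invalid_not_nan_propagation(self, fluor, grid):
        curve = self.make_curve_with_reset(fluor, grid, background_rate=3000.0)
        bpar, bperp = estimate_background(curve)
        reset = curve.select("reset")
        tail = slice(len(reset.bin_centers) // 2, None)
        from starss.schemes import DecayCurve

        bg_only = DecayCurve(
            reset.bin_centers[tail], reset.counts_parallel[tail],
            reset.counts_perpendicular[tail], reset.bin_widths[tail],
            np.asarray(["probe"] * len(reset.bin_centers[tail]), dtype=object), {},
        )
        a = compute_anisotropy(bg_only, background=(bpar, bperp))
        assert not a.valid.all()
        assert np.isnan(a.r[~a.valid]).all()


class TestSchemeValidation:
    def test_multi_cycle_needs_reset(self, fluor):
        seg = SchemeSegment(1e-3, Illumination(role="probe_488", polarization="circular",
                                               power_density=1.0, duration=1e-3),
                            detect=True, bin_width=1e-4, label="probe")
        with pytest.raises(ValueError, match="reset"):
            PulseScheme((seg,), cycles=2)

    def test_bin_width_floor(self):
        ill = Illumination(role="probe_488", polarization="circular",
                           power_density=1.0, duration=1e-3)
        with pytest.raises(ValueError, match="bin_width"):
            SchemeSegment(1e-3, ill, detect=True, bin_width=1e-9)

    def test_substreams_are_independent(self):
        a = substream(3, "alpha").integers(0, 2**31, 8)
        b = substream(3, "beta").integers(0, 2**31, 8)
        a2 = substream(3, "alpha").integers(0, 2**31, 8)
        assert not np.array_equal(a, b)
        np.testing.assert_array_equal(a, a2)
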