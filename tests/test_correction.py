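"""Phase aberration correction: analytic, ray-traced, and time-reversal."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skullbeam.acoustics import ArraySpec, map_hu_to_medium, simulate_forward
from skullbeam.correction import (PhaseVector, delay_from_phase,
                                  estimate_arrival_delays,
                                  geometric_focus_phases, ray_trace_phases,
                                  time_reversal_phases, wrap_phase)
from skullbeam.phantoms import SkullSlice, element_positions, generate_skull_phantom


class TestPhaseVector:
    def test_delays_normalized_to_min_zero(self):
        pv = PhaseVector(delays_s=np.array([3e-6, 1e-6, 2e-6]), f0_hz=250e3)
        assert pv.delays_s.min() == 0.0
        assert np.allclose(pv.delays_s, [2e-6, 0.0, 1e-6])

    def test_phase_convention(self):
        period = 1 / 250e3
        pv = PhaseVector(delays_s=np.array([0.0, period / 4, period]), f0_hz=250e3)
        assert pv.phases_rad[0] == pytest.approx(0.0)
        assert pv.phases_rad[1] == pytest.approx(np.pi / 2)
        assert pv.phases_rad[2] == pytest.approx(0.0, abs=1e-9)  # full period wraps

    def test_wrap_full_period_is_zero(self):
        period = 1 / 500e3
        pv = wrap_phase(PhaseVector(delays_s=np.array([0.0, period]), f0_hz=500e3))
        assert np.allclose(pv.delays_s, 0.0, atol=1e-15)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1e-5), min_size=2, max_size=8))
    def test_phase_roundtrip(self, delays):
        pv = wrap_phase(PhaseVector(delays_s=np.array(delays), f0_hz=500e3))
        back = wrap_phase(delay_from_phase(pv.phases_rad, 500e3))
        assert np.allclose(back.phases_rad, pv.phases_rad, atol=1e-6)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            PhaseVector(delays_s=np.zeros(4), f0_hz=0.0)


class TestGeometricFocus:
    def test_three_four_five_travel_time(self):
        """Element 40 mm off-axis, target 30 mm deep: path 50 mm at 1500 m/s
        is 13.33 us longer than the 30 mm on-axis path (20 us vs 33.33 us)."""
        array = ArraySpec(n_elements=9, pitch_mm=10.0, standoff_mm=0.0,
                          f0_hz=500e3)
        # 1 mm pixels: elements span cols 20..100 on row 0, center col 60
        pv = geometric_focus_phases(1500.0, array, (30, 60), 1.0, shape=(121, 121))
        # the center element (shortest path) waits for the edge elements
        extra_path_delay = pv.delays_s[4] - pv.delays_s[0]
        assert extra_path_delay == pytest.approx((0.05 - 0.03) / 1500.0, rel=1e-9)
        assert pv.delays_s[0] == pytest.approx(0.0)  # outermost fires first...
        assert np.allclose(pv.delays_s, pv.delays_s[::-1])  # symmetric target

    def test_matches_ray_tracing_in_uniform_medium(self, desk64):
        _, array, config = desk64
        sl = SkullSlice(hu_grid=np.zeros((64, 64)), pixel_spacing_mm=config.pixel_spacing_mm)
        med = map_hu_to_medium(sl)
        c0 = float(med.speed[0, 0])
        geo = geometric_focus_phases(c0, array, (44, 25), config.pixel_spacing_mm,
                                     shape=(64, 64))
        ray = ray_trace_phases(med, array, (44, 25))
        assert np.allclose(ray.delays_s, geo.delays_s, atol=1e-9)


class TestRayTracing:
    @staticmethod
    def _slab_slice(spacing, thickness_px, hu=1500.0, n=64):
        hu_grid = np.zeros((n, n))
        hu_grid[10:10 + thickness_px, :] = hu
        return SkullSlice(hu_grid=hu_grid, pixel_spacing_mm=spacing)

    def test_uniform_slab_matches_analytic_secant_model(self, desk64):
        """Extra delay through a flat slab is (1/c_s - 1/c_w) * t * sec(theta)."""
        _, array, config = desk64
        dx = config.pixel_spacing_mm
        sl = self._slab_slice(dx, thickness_px=6)
        med = map_hu_to_medium(sl)
        c_w = float(med.speed[0, 0])
        c_s = float(med.speed[12, 0])
        target = (50, 32)
        ray = ray_trace_phases(med, array, target)
        els = np.array(element_positions((64, 64), dx, array.n_elements,
                                         array.pitch_mm, array.standoff_mm), float)
        d_px = np.hypot(els[:, 0] - target[0], els[:, 1] - target[1])
        sec = d_px / (target[0] - els[:, 0])  # 1/cos(theta) per element
        t_analytic = (d_px * dx * 1e-3) / c_w + 6 * dx * 1e-3 * sec * (1 / c_s - 1 / c_w)
        expect = t_analytic.max() - t_analytic
        # bilinear edge pixels blur the slab boundary: allow a fraction of
        # the single-pixel slowness difference
        tol = dx * 1e-3 * abs(1 / c_s - 1 / c_w)
        assert np.allclose(ray.delays_s, expect, atol=tol)

    def test_wedge_ordering_matches_oversampled_integral(self, desk64):
        """Wedge-thickness slab: delay ordering equals a fine brute-force
        line integral done independently of the implementation."""
        _, array, config = desk64
        dx = config.pixel_spacing_mm
        hu = np.zeros((64, 64))
        for c in range(64):
            hu[10:10 + 2 + c * 8 // 64, c] = 1500.0  # thickness grows with col
        med = map_hu_to_medium(SkullSlice(hu_grid=hu, pixel_spacing_mm=dx))
        target = (50, 32)
        ray = ray_trace_phases(med, array, target)
        els = element_positions((64, 64), dx, array.n_elements,
                                array.pitch_mm, array.standoff_mm)
        times = []
        for (er, ec) in els:
            n_s = 4000
            s = np.linspace(0.0, 1.0, n_s)
            rr = er + (target[0] - er) * s
            cc = ec + (target[1] - ec) * s
            # independent bilinear interpolation of the speed map
            r0 = np.clip(np.floor(rr).astype(int), 0, 62)
            c0 = np.clip(np.floor(cc).astype(int), 0, 62)
            fr, fc = rr - r0, cc - c0
            c_interp = (med.speed[r0, c0] * (1 - fr) * (1 - fc)
                        + med.speed[r0 + 1, c0] * fr * (1 - fc)
                        + med.speed[r0, c0 + 1] * (1 - fr) * fc
                        + med.speed[r0 + 1, c0 + 1] * fr * fc)
            length_m = np.hypot(target[0] - er, target[1] - ec) * dx * 1e-3
            times.append(np.trapezoid(1.0 / c_interp, dx=length_m / (n_s - 1)))
        expect = np.array(times)
        expect = expect.max() - expect
        assert np.array_equal(np.argsort(ray.delays_s), np.argsort(expect))
        assert np.allclose(ray.delays_s, expect, atol=5e-9)


class TestTimeReversal:
    def test_water_delays_match_analytic_oracle(self, water64, desk64):
        _, array, config = desk64
        target = (44, 25)
        tr = time_reversal_phases(water64, array, target, config)
        geo = geometric_focus_phases(1500.0, array, target,
                                     config.pixel_spacing_mm, shape=(64, 64))
        # full-wave arrivals carry small near-field diffraction phase shifts
        # relative to straight-line geometry: allow two solver steps
        dt = 0.3 * config.dx_m / 1500.0
        assert np.allclose(tr.delays_s, geo.delays_s, atol=2 * dt)

    def test_symmetric_medium_gives_palindromic_delays(self, fixed_phantom_spec):
        import dataclasses

        from skullbeam.acoustics import SimConfig

        # odd grid: plate center, target, and array share one symmetry axis
        spec = dataclasses.replace(fixed_phantom_spec, grid_size_native=65,
                                   pixel_spacing_mm=60.0 / 65)
        _, array, _ = __import__("skullbeam").pipeline.desk_setup(64)
        config = SimConfig(window_mm=60.0, grid_n=65, pml_px=12)
        sl = generate_skull_phantom(spec, seed=0)
        med = map_hu_to_medium(sl)
        tr = time_reversal_phases(med, array, (44, 32), config)
        assert np.allclose(tr.delays_s, tr.delays_s[::-1], atol=1e-9)

    def test_amplitude_invariance_of_delay_estimator(self, water64, desk64):
        from skullbeam.acoustics import record_at_elements

        _, array, config = desk64
        traces = record_at_elements(water64, (44, 25), array, config)
        tau1 = estimate_arrival_delays(traces, array.f0_hz, array.n_cycles)
        traces.traces = traces.traces * 37.5
        tau2 = estimate_arrival_delays(traces, array.f0_hz, array.n_cycles)
        assert np.allclose(tau1, tau2, atol=1e-15)

    def test_correction_raises_focal_pressure_on_aberrator(self, desk64):
        spec, array, config = desk64
        sl = generate_skull_phantom(spec, seed=1)
        med = map_hu_to_medium(sl)
        target = (44, 32)
        tr = time_reversal_phases(med, array, target, config)
        corrected = simulate_forward(med, array, tr.delays_s, config)
        uncorrected = simulate_forward(med, array, np.zeros(array.n_elements), config)
        assert corrected.field[target] > uncorrected.field[target]

    def test_xcorr_estimator_agrees_with_fourier(self, water64, desk64):
        _, array, config = desk64
        target = (44, 25)
        tr_f = time_reversal_phases(water64, array, target, config, method="fourier")
        tr_x = time_reversal_phases(water64, array, target, config, method="xcorr")
        # envelope-peak picking is step-quantized and biased by the
        # cylindrical-wave tail on oblique paths: agree to a quarter period
        assert np.allclose(tr_f.delays_s, tr_x.delays_s, atol=0.25 / array.f0_hz)
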