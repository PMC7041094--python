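import numpy as np
import pytest
from scipy.integrate import quad

import blotkin as bk
from blotkin import KineticConstants, KineticsError, SpotTrace, ce_for_signal, \
    fit_ce, fit_kappa, light_flux_model, measure_spot_traces, quantify
from blotkin.background import background_series


def intensity_quadrature(t, kappa, ce, constants):
    """Independent oracle: numerically integrate the instantaneous light
    intensity I(t') = kappa * k_r * C_E * exp(-k_r C_E (t' + t0)) over the
    exposure interval [0, t]."""
    a = constants.k_r * ce

    def integrand(u):
        return kappa * a * np.exp(-a * (u + constants.t0))

    val, _ = quad(integrand, 0.0, t, epsabs=1e-14, epsrel=1e-12)
    return val


class TestLightFluxModel:
    def test_zero_time_gives_zero(self, constants):
        assert light_flux_model(0.0, 2.5, 1e-9, constants) == 0.0

    def test_asymptote(self, constants):
        ce = 5e-9
        a = constants.k_r * ce
        expected = 3.0 * np.exp(-a * constants.t0)
        assert np.isclose(light_flux_model(1e9, 3.0, ce, constants), expected,
                          rtol=1e-9)

    def test_known_value_against_quadrature(self):
        constants = KineticConstants(t0=0.0)
        ce = 0.01 / constants.k_r  # k_r * C_E = 0.01 / s
        got = light_flux_model(100.0, 1.0, ce, constants)
        assert abs(got - (1 - np.exp(-1))) < 1e-12
        oracle = intensity_quadrature(100.0, 1.0, ce, constants)
        assert abs(got - oracle) < 1e-8

    def test_matches_quadrature_on_grid(self, constants):
        for ce in np.geomspace(1e-10, 1e-7, 6):
            for t in np.geomspace(1, 600, 6):
                got = light_flux_model(t, 1.3, ce, constants)
                oracle = intensity_quadrature(t, 1.3, ce, constants)
                assert abs(got - oracle) <= 1e-6 * max(abs(oracle), 1e-300)

    def test_monotone_in_time_and_concave(self, constants):
        t = np.linspace(0.0, 600.0, 200)
        for ce in np.geomspace(1e-10, 1e-7, 8):
            L = light_flux_model(t, 1.0, ce, constants)
            assert np.all(np.diff(L) >= -1e-18)   # flat only at the plateau
            assert L[1] > L[0]
            assert np.all(np.diff(L, 2) <= 1e-15)

    def test_monotone_in_ce_below_turnover(self, constants):
        # below the turnover of the amplitude factor exp(-a t0)(1-exp(-a t))
        t = 60.0
        ces = np.geomspace(1e-11, 1e-9, 20)
        L = np.array([light_flux_model(t, 1.0, ce, constants) for ce in ces])
        assert np.all(np.diff(L) > 0)

    def test_ce_for_signal_inverts_model(self, constants):
        ce = 3e-9
        target = light_flux_model(300.0, 0.8, ce, constants)
        back = ce_for_signal(target, 0.8, 300.0, constants)
        assert np.isclose(back, ce, rtol=1e-9)
        assert ce_for_signal(0.0, 1.0, 100.0, constants) == 0.0


def model_traces(layout, kappa, ce_map, times, constants, sat=None):
    traces = []
    for rc in layout.grid_spots:
        L = light_flux_model(times, kappa, ce_map[rc], constants)
        flags = np.zeros_like(times, bool) if sat is None else sat(L)
        traces.append(SpotTrace(spot=rc, L=L, times=times,
                                saturated_frames=flags))
    return traces


class TestFitKappa:
    def test_noiseless_recovery(self, small_layout, constants):
        times = np.geomspace(5, 600, 15)
        rng = np.random.default_rng(0)
        ce_map = {rc: v for rc, v in zip(
            small_layout.grid_spots,
            rng.permutation(np.geomspace(1e-10, 5e-9, 20)))}
        traces = model_traces(small_layout, 2.0, ce_map, times, constants)
        kappa, provisional, _ = fit_kappa(traces, constants)
        assert abs(kappa - 2.0) / 2.0 < 1e-6
        for rc, ce in provisional.items():
            assert abs(ce - ce_map[rc]) / ce_map[rc] < 1e-6

    def test_scaling_traces_scales_kappa_only(self, small_layout, constants):
        times = np.geomspace(5, 600, 15)
        ce_map = {rc: v for rc, v in zip(
            small_layout.grid_spots, np.geomspace(1e-10, 5e-9, 20))}
        traces = model_traces(small_layout, 2.0, ce_map, times, constants)
        scaled = [SpotTrace(tr.spot, 3.0 * tr.L, tr.times,
                            tr.saturated_frames) for tr in traces]
        kappa, provisional, _ = fit_kappa(scaled, constants)
        assert abs(kappa - 6.0) / 6.0 < 1e-6
        for rc, ce in provisional.items():
            assert abs(ce - ce_map[rc]) / ce_map[rc] < 1e-6

    def test_fewer_traces_than_requested_warns(self, constants):
        times = np.geomspace(5, 600, 10)
        traces = [
            SpotTrace((0, i), light_flux_model(times, 1.0, 1e-9, constants),
                      times, np.zeros_like(times, bool))
            for i in range(4)
        ]
        with pytest.warns(UserWarning, match="4 usable traces"):
            kappa, provisional, _ = fit_kappa(traces, constants, n_spots=10)
        assert len(provisional) == 4
        assert abs(kappa - 1.0) < 1e-6


class TestFitCe:
    def test_noiseless_recovery(self, constants):
        times = np.geomspace(5, 600, 20)
        ce = 5e-9
        tr = SpotTrace((0, 0), light_flux_model(times, 1.7, ce, constants),
                       times, np.zeros_like(times, bool))
        got, resid = fit_ce(tr, 1.7, constants)
        assert abs(got - ce) / ce < 1e-6
        assert resid < 1e-12

    def test_fast_decay_recovery_with_saturation_mask(self, constants):
        # post-turnover spot observed only on early frames
        times = np.geomspace(5, 600, 20)
        ce = 2e-8
        L = light_flux_model(times, 1.0, ce, constants)
        tr = SpotTrace((0, 0), L, times, times > 60.0)
        got, _ = fit_ce(tr, 1.0, constants)
        assert abs(got - ce) / ce < 1e-6

    def test_all_zero_trace(self, constants):
        times = np.linspace(10, 100, 5)
        tr = SpotTrace((0, 0), np.zeros(5), times, np.zeros(5, bool))
        assert fit_ce(tr, 1.0, constants)[0] == 0.0

    def test_all_frames_excluded(self, constants):
        times = np.linspace(10, 100, 5)
        tr = SpotTrace((0, 0), np.ones(5), times, np.ones(5, bool))
        with pytest.raises(KineticsError, match="saturated"):
            fit_ce(tr, 1.0, constants)

    def test_noisy_recovery_95th_percentile(self, constants):
        # 1% multiplicative noise at peak SNR 100: 95th-percentile error < 5%
        times = np.geomspace(5, 600, 20)
        ce = 2e-9
        clean = light_flux_model(times, 1.0, ce, constants)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean * (1 + 0.01 * rng.standard_normal(times.size))
            tr = SpotTrace((0, 0), noisy, times, np.zeros_like(times, bool))
            got, _ = fit_ce(tr, 1.0, constants)
            errs.append(abs(got - ce) / ce)
        assert np.percentile(errs, 95) < 0.05

    def test_rank_preservation(self, small_layout, constants):
        times = np.geomspace(5, 600, 15)
        ces = np.geomspace(1e-10, 1e-9, 20)
        ce_map = dict(zip(small_layout.grid_spots, ces))
        traces = model_traces(small_layout, 1.0, ce_map, times, constants)
        kappa, _, _ = fit_kappa(traces, constants)
        fitted = [fit_ce(tr, kappa, constants)[0] for tr in traces]
        order_true = np.argsort([ce_map[tr.spot] for tr in traces])
        np.testing.assert_array_equal(np.argsort(fitted), order_true)


class TestMeasureSpotTraces:
    def test_constant_frame_cancels_background(self, small_layout):
        v = 0.25
        frames = np.full((3, *small_layout.grid_shape), v)
        stack = bk.from_frames(frames, times=[1, 2, 3])
        bg = background_series(stack)
        traces = measure_spot_traces(stack, small_layout, bg)
        for tr in traces:
            assert np.abs(tr.L).max() < 1e-12

    def test_geometry_mismatch(self, small_layout):
        stack = bk.from_frames(np.zeros((3, 10, 10)), times=[1, 2, 3])
        bg = background_series(stack)
        with pytest.raises(KineticsError, match="geometry"):
            measure_spot_traces(stack, small_layout, bg)

    def test_spot_box_mean_matches_generator_normalization(
            self, small_layout, constants):
        # noiseless, aligned: the generator guarantees box mean == L(t)
        truth = bk.default_truth(small_layout, seed=0, rotation_deg=0.0,
                                 translation_px=(0.0, 0.0), margin_px=0,
                                 bg_intercept=0.0, bg_slope=0.0,
                                 sigma_intercept=0.0, sigma_slope=0.0,
                                 kappa=0.1)
        stack, full = bk.generate_stack(small_layout, truth)
        bg = background_series(stack)
        traces = measure_spot_traces(stack, small_layout, bg)
        for tr in traces:
            box_mean = tr.L + bg.b          # undo background subtraction
            expected = full.per_spot_L[tr.spot]
            mask = expected > 1e-3
            rel = np.abs(box_mean[mask] - expected[mask]) / expected[mask]
            assert rel.max() < 0.01


class TestQuantify:
    def test_end_to_end_recovery(self, small_layout, constants):
        truth = bk.default_truth(small_layout, seed=2, margin_px=60)
        stack, full = bk.generate_stack(small_layout, truth)
        fit = quantify(stack, small_layout, constants)
        refs = set(small_layout.reference_spots)
        errs = [abs(fit.ce_per_spot[s] - full.ce_map[s]) / full.ce_map[s]
                for s in fit.ce_per_spot if s not in refs]
        assert np.percentile(errs, 95) < 0.05
        assert abs(fit.kappa - truth.kappa) / truth.kappa < 0.02

    def test_background_only_stack_below_detection_floor(
            self, small_layout, constants):
        # all analytes absent; only the reference landmarks glow
        truth = bk.default_truth(small_layout, seed=3, margin_px=60)
        truth.ce_map = {rc: (truth.ce_map[rc]
                             if rc in small_layout.reference_spots else 0.0)
                        for rc in truth.ce_map}
        stack, full = bk.generate_stack(small_layout, truth)
        fit = quantify(stack, small_layout, constants)
        t_end = stack.exposure_times[-1]
        sigma_end = fit.background.sigma_b[-1]
        floor = ce_for_signal(2.0 * sigma_end, fit.kappa, t_end, constants)
        for s, ce in fit.ce_per_spot.items():
            if s not in small_layout.reference_spots:
                assert ce <= floor

    def test_missing_times_refused(self, small_layout, constants):
        stack = bk.from_frames(np.zeros((3, *small_layout.grid_shape)))
        with pytest.raises(KineticsError, match="exposure times"):
            quantify(stack, small_layout, constants)

    def test_too_few_frames_refused(self, small_layout, constants):
        stack = bk.from_frames(np.zeros((2, *small_layout.grid_shape)),
                               times=[1.0, 2.0])
        with pytest.raises(KineticsError, match="3 frames"):
            quantify(stack, small_layout, constants)
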