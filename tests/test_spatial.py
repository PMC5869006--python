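"""Movie-level analysis: ROIs, kymographs, phase maps, waves, synchrony."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import clockwave as cw


def _uniform_phase_movie(seed=4, duration=1500.0):
    """Spatially synchronous colony (wave speed effectively infinite)."""
    cfg = cw.ColonySimConfig(seed=seed, noise_model="none",
                             wave_speed_um_per_min=1e9, duration_min=duration)
    truth = cw.simulate_phase_field(cfg)
    return cfg, truth, cw.render_luminescence(truth, cfg)


class TestRoiTrace:
    def test_single_pixel_rect_is_pixel_time_course(self, noiseless_colony):
        _, _, movie = noiseless_colony
        ts = cw.roi_trace(movie, cw.ROI.make_rect(10, 20, 11, 21))
        np.testing.assert_array_equal(ts.value, movie.frames[:, 10, 20])

    def test_whole_frame_rect_proportional_to_pmt(self, noiseless_colony):
        _, _, movie = noiseless_colony
        t, h, w = movie.frames.shape
        ts = cw.roi_trace(movie, cw.ROI.make_rect(0, 0, h, w))
        pmt = cw.integrate_to_pmt(movie, exposure_s=5.0)
        np.testing.assert_allclose(ts.value * h * w / 5.0, pmt.value, rtol=1e-12)

    def test_off_colony_rect_is_baseline_plus_drift(self, noiseless_colony):
        cfg, _, movie = noiseless_colony
        ts = cw.roi_trace(movie, cw.ROI.make_rect(0, 0, 2, 2))  # far corner
        expect = cfg.baseline_cps + cfg.baseline_drift_per_min * cfg.time_min
        np.testing.assert_allclose(ts.value, expect, atol=1e-9)

    def test_out_of_bounds_rejected(self, noiseless_colony):
        _, _, movie = noiseless_colony
        with pytest.raises(ValueError, match="outside"):
            cw.roi_trace(movie, cw.ROI.make_rect(0, 0, 65, 10))


class TestKymograph:
    def test_constant_frames_give_constant_columns(self):
        c = np.arange(2, 42, dtype=float)
        frames = np.broadcast_to(c[:, None, None], (40, 16, 16)).copy()
        movie = cw.MovieStack(frames, interval_min=5.0, pixel_um=2.0)
        k = cw.compute_kymograph(movie, cw.ROI.make_polyline([(8, 1), (8, 14)]))
        for j in range(40):
            np.testing.assert_allclose(k.matrix[:, j], c[j], atol=1e-9)

    def test_columns_in_temporal_order(self, noiseless_colony):
        _, _, movie = noiseless_colony
        k = cw.compute_kymograph(movie, cw.ROI.make_polyline([(31, 31), (31, 60)]))
        np.testing.assert_array_equal(k.time_min, movie.time_min)
        assert k.matrix.shape == (k.arc_um.size, movie.frames.shape[0])

    def test_linear_in_intensities(self, noiseless_colony):
        _, _, movie = noiseless_colony
        roi = cw.ROI.make_polyline([(10, 10), (50, 50)])
        k1 = cw.compute_kymograph(movie, roi)
        doubled = cw.MovieStack(2 * movie.frames, interval_min=movie.interval_min,
                                pixel_um=movie.pixel_um)
        k2 = cw.compute_kymograph(doubled, roi)
        np.testing.assert_allclose(k2.matrix, 2 * k1.matrix, rtol=1e-12)

    def test_degenerate_polyline_rejected(self, noiseless_colony):
        _, _, movie = noiseless_colony
        with pytest.raises(ValueError, match="degenerate"):
            cw.compute_kymograph(movie, cw.ROI.make_polyline([(5, 5), (5, 5)]))


class TestPhaseMovie:
    def test_noiseless_phase_recovered(self, noiseless_colony):
        cfg, truth, movie = noiseless_colony
        pm = cw.phase_movie(movie)
        t = movie.frames.shape[0]
        interior = slice(40, t - 40)
        diff = cw.wrap_phase(pm.phase[interior][:, pm.mask]
                             - truth.phase[interior][:, pm.mask])
        rms = float(np.sqrt(np.mean(diff ** 2)))
        assert rms < 0.3

    def test_off_colony_pixels_masked(self, noiseless_colony):
        cfg, truth, movie = noiseless_colony
        pm = cw.phase_movie(movie)
        cy, cx = cfg.center
        yy, xx = np.mgrid[0:cfg.height_px, 0:cfg.width_px]
        r = np.hypot(yy - cy, xx - cx) * cfg.pixel_um
        assert not pm.mask[r > cfg.colony_radius_um + 2 * cfg.pixel_um].any()
        assert pm.mask[r < cfg.colony_radius_um / 2].all()

    def test_uniform_phase_movie_spatially_coherent(self):
        _, truth, movie = _uniform_phase_movie()
        pm = cw.phase_movie(movie)
        t = movie.frames.shape[0]
        for ti in range(50, t - 50, 50):
            vals = pm.phase[ti][pm.mask]
            mean = np.angle(np.exp(1j * vals).mean())
            disp = np.sqrt(np.mean(cw.wrap_phase(vals - mean) ** 2))
            assert disp < 0.1

    def test_all_masked_is_hard_error(self, noiseless_colony):
        _, _, movie = noiseless_colony
        with pytest.raises(ValueError, match="threshold"):
            cw.phase_movie(movie, intensity_threshold=1e12)


class TestPhaseLag:
    def test_known_delay_recovered(self):
        t = 5.0 * np.arange(577)
        p = 160.0
        a = cw.TimeSeries(t, np.cos(2 * np.pi * t / p), "a")
        b = cw.TimeSeries(t, np.cos(2 * np.pi * (t - 30.0) / p), "b")
        lag = cw.phase_lag(cw.hilbert_phase(a), cw.hilbert_phase(b),
                           window=slice(30, -30))
        assert lag["radians"] == pytest.approx(2 * np.pi * 30 / p, abs=0.05)
        assert lag["minutes"] == pytest.approx(30.0, abs=5.0)

    def test_identical_traces_zero_lag(self, cosine_trace):
        ph = cw.hilbert_phase(cosine_trace)
        lag = cw.phase_lag(ph, ph)
        assert lag["radians"] == pytest.approx(0.0, abs=1e-12)

    def test_center_leads_periphery_by_travel_time(self, noiseless_colony):
        cfg, _, movie = noiseless_colony
        t = movie.frames.shape[0]
        cy, cx = int(cfg.center[0]), int(cfg.center[1])
        central = cw.roi_trace(movie, cw.ROI.make_rect(cy, cx, cy + 1, cx + 1))
        periph = cw.roi_trace(movie, cw.ROI.make_rect(cy, cx + 15, cy + 1, cx + 16))
        lag = cw.phase_lag(cw.hilbert_phase(cw.preprocess_pmt(central)),
                           cw.hilbert_phase(cw.preprocess_pmt(periph)),
                           window=slice(40, t - 40))
        r_c = np.hypot(cy - cfg.center[0], cx - cfg.center[1]) * cfg.pixel_um
        r_p = np.hypot(cy - cfg.center[0], cx + 15 - cfg.center[1]) * cfg.pixel_um
        expect = 2 * np.pi * (r_p - r_c) / (cfg.period_min * cfg.wave_speed_um_per_min)
        assert lag["radians"] > 0  # center leads
        assert lag["radians"] == pytest.approx(expect, rel=0.05)

    def test_mismatched_grids_rejected(self, cosine_trace):
        ph = cw.hilbert_phase(cosine_trace)
        short = cw.TimeSeries(cosine_trace.time_min[:100], cosine_trace.value[:100], "s")
        with pytest.raises(ValueError, match="grid"):
            cw.phase_lag(ph, cw.hilbert_phase(short))


class TestLocateCenter:
    def test_single_focus_found_within_3px(self, noiseless_colony):
        cfg, _, movie = noiseless_colony
        pm = cw.phase_movie(movie)
        y, x, lead = cw.locate_center(pm)
        assert np.hypot(y - cfg.center[0], x - cfg.center[1]) <= 3.0
        assert lead > 0

    def test_uniform_phase_reports_near_zero_lead(self):
        _, _, movie = _uniform_phase_movie()
        pm = cw.phase_movie(movie)
        _, _, lead = cw.locate_center(pm)
        assert abs(lead) < 0.1

    def test_two_focus_movie_one_center_per_component(self):
        cfg_a = cw.ColonySimConfig(seed=3, noise_model="none", center_xy=(16, 16),
                                   colony_radius_um=50, duration_min=1500)
        cfg_b = cw.ColonySimConfig(seed=3, noise_model="none", center_xy=(48, 48),
                                   colony_radius_um=50, duration_min=1500)
        ma = cw.render_luminescence(cw.simulate_phase_field(cfg_a), cfg_a)
        mb = cw.render_luminescence(cw.simulate_phase_field(cfg_b), cfg_b)
        fused = cw.MovieStack(ma.frames + mb.frames - cfg_a.baseline_cps,
                              interval_min=5.0, pixel_um=4.0)
        pm = cw.phase_movie(fused)
        labels, n = ndimage.label(pm.mask)
        assert n == 2
        centers = {(16, 16): False, (48, 48): False}
        for i in range(1, n + 1):
            y, x, _ = cw.locate_center(pm, mask=labels == i)
            for (cy, cx) in centers:
                if np.hypot(y - cy, x - cx) <= 3.0:
                    centers[(cy, cx)] = True
        assert all(centers.values())


class TestWaveSpeed:
    @pytest.mark.parametrize("v", [0.5, 1.0, 2.0])
    def test_configured_speed_recovered_within_10pct(self, v):
        cfg = cw.ColonySimConfig(seed=4, noise_model="none", wave_speed_um_per_min=v,
                                 colony_radius_um=120.0, duration_min=2880)
        movie = cw.render_luminescence(cw.simulate_phase_field(cfg), cfg)
        cy, cx = cfg.center
        k = cw.compute_kymograph(movie, cw.ROI.make_polyline([(cy, cx), (cy, 62)]))
        ws = cw.wave_speed(k)
        assert ws.finite
        assert ws.speed_um_per_min == pytest.approx(v, rel=0.10)

    def test_standing_oscillation_reports_no_finite_speed(self):
        _, _, movie = _uniform_phase_movie()
        k = cw.compute_kymograph(movie, cw.ROI.make_polyline([(31.5, 31.5), (31.5, 62)]))
        ws = cw.wave_speed(k)
        assert not ws.finite
        assert np.isinf(ws.speed_um_per_min)

    def test_doubling_pixel_size_doubles_speed(self):
        cfg = cw.ColonySimConfig(seed=4, noise_model="none", duration_min=2000)
        movie = cw.render_luminescence(cw.simulate_phase_field(cfg), cfg)
        cy, cx = cfg.center
        k = cw.compute_kymograph(movie, cw.ROI.make_polyline([(cy, cx), (cy, 62)]))
        k2 = cw.Kymograph(k.matrix, 2 * k.arc_um, k.time_min)
        assert cw.wave_speed(k2).speed_um_per_min == pytest.approx(
            2 * cw.wave_speed(k).speed_um_per_min, rel=1e-6)


class TestSyncIndex:
    def test_identical_phases_give_exactly_one(self, cosine_trace):
        ph = cw.hilbert_phase(cosine_trace)
        _, r = cw.sync_index([ph, ph, ph])
        assert r == 1.0

    def test_uniform_random_phases_incoherent(self):
        t = 5.0 * np.arange(200)
        low = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            traces = []
            for i in range(100):
                phi0 = rng.uniform(-np.pi, np.pi)
                wrapped = cw.wrap_phase(2 * np.pi * t / 167.0 + phi0)
                traces.append(cw.PhaseTrace(t, wrapped, np.unwrap(wrapped),
                                            np.ones(t.size), str(i)))
            _, r = cw.sync_index(traces)
            low += r < 0.2
        assert low == 5

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.floats(-np.pi, np.pi))
    def test_invariant_under_global_phase_shift(self, shift):
        t = 5.0 * np.arange(100)
        rng = np.random.default_rng(0)
        traces, shifted = [], []
        for i in range(10):
            w = cw.wrap_phase(2 * np.pi * t / 167.0 + rng.uniform(-1, 1))
            traces.append(cw.PhaseTrace(t, w, np.unwrap(w), np.ones(t.size), str(i)))
            ws = cw.wrap_phase(w + shift)
            shifted.append(cw.PhaseTrace(t, ws, np.unwrap(ws), np.ones(t.size), str(i)))
        _, r1 = cw.sync_index(traces)
        _, r2 = cw.sync_index(shifted)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_fewer_than_two_traces_rejected(self, cosine_trace):
        with pytest.raises(ValueError):
            cw.sync_index([cw.hilbert_phase(cosine_trace)])
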