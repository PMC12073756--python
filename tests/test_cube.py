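"""Cube reconstruction tests: shear, onsets, wavelength map, interpolation."""

import numpy as np
import pytest

import algascan as ag
from algascan.cube import (
    ChannelTrimWindows,
    MonoStack,
    ShiftModel,
    WavelengthMap,
    _xcorr_lag,
    build_wavelength_map,
    default_band_grid,
    deshear_stack,
    detect_onsets,
    estimate_row_shift,
    fit_shift_model,
    frames_to_wavelength,
    interpolate_bands,
    trim_and_sum_channels,
)


def brute_force_lag(a, b):
    """Independent oracle: Pearson correlation at every integer lag."""
    n = len(a)
    best, best_r = 0, -np.inf
    for k in range(-(n - n // 4), n - n // 4 + 1):
        if k >= 0:
            sa, sb = a[k:], b[: n - k]
        else:
            sa, sb = a[: n + k], b[-k:]
        if sa.std() == 0 or sb.std() == 0:
            continue
        r = np.corrcoef(sa, sb)[0, 1]
        if r > best_r:
            best, best_r = k, r
    return best


class TestRowShift:
    def _stack_from_traces(self, top, bottom, row_top=0, row_bottom=9):
        n = len(top)
        stack = np.zeros((n, 10, 1, 3))
        stack[:, row_top, 0, :] = np.asarray(top)[:, None]
        stack[:, row_bottom, 0, :] = np.asarray(bottom)[:, None]
        return stack

    def test_identical_traces_give_zero_lag(self):
        f = np.arange(120.0)
        trace = np.exp(-0.5 * ((f - 60) / 10) ** 2)
        stack = self._stack_from_traces(trace, trace)
        assert estimate_row_shift(stack, 0, 0, 9) == pytest.approx(0.0, abs=1e-6)

    def test_integer_shift_recovered_exactly(self):
        f = np.arange(160.0)
        g = lambda x: np.exp(-0.5 * ((x - 80) / 12) ** 2)
        top, bottom = g(f), g(f + 7)  # bottom leads by 7 frames
        stack = self._stack_from_traces(top, bottom)
        lag = estimate_row_shift(stack, 0, 0, 9)
        assert lag == pytest.approx(7.0, abs=0.05)
        assert brute_force_lag(top, bottom) == 7

    def test_flat_trace_rejected(self):
        stack = np.zeros((50, 10, 1, 3))
        with pytest.raises(ValueError, match="flat"):
            estimate_row_shift(stack, 0, 0, 9)

    def test_simulator_lag_matches_ground_truth(self, demo_scan):
        stack_obj, _ = demo_scan
        linear = stack_obj.counts.astype(float) / 255.0
        lag = estimate_row_shift(linear, 80, 8, 108)
        expected = stack_obj.scan.shift_slope * 100
        assert lag == pytest.approx(expected, rel=0.02)


class TestShiftModel:
    def test_single_pair_one_point_line(self):
        assert fit_shift_model([(100.0, 25.0)]).slope == pytest.approx(0.25)

    def test_exact_lags_recover_slope(self):
        pairs = [(dr, 0.1 * dr) for dr in (40.0, 80.0, 120.0)]
        assert fit_shift_model(pairs).slope == pytest.approx(0.1)

    def test_noisy_lags_match_closed_form(self):
        rng = np.random.default_rng(0)
        dr = np.array([30.0, 60.0, 90.0, 120.0])
        lag = 0.2 * dr + rng.normal(0, 0.5, 4)
        model = fit_shift_model(list(zip(dr, lag)))
        assert model.slope == pytest.approx(np.sum(dr * lag) / np.sum(dr * dr))

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_shift_model([(0.0, 1.0), (0.0, 2.0)])
        with pytest.raises(ValueError):
            fit_shift_model([])


class TestDeshear:
    def test_zero_slope_is_identity(self):
        stack = np.random.default_rng(0).random((20, 6, 4, 3))
        mono = deshear_stack(stack, ShiftModel(0.0))
        assert np.array_equal(mono.data, stack)
        assert np.array_equal(mono.frame_indices, np.arange(20))

    def test_valid_frame_count_bound(self):
        stack = np.zeros((240, 128, 2, 3))
        mono = deshear_stack(stack, ShiftModel(0.2))
        assert mono.n_frames >= 240 - int(np.ceil(0.2 * 128))

    def test_residual_lag_below_one_frame(self, demo_scan, demo_result):
        # oracle: re-estimating the shift on the de-sheared stack must find
        # (almost) nothing left
        stack_obj, _ = demo_scan
        linear = stack_obj.counts.astype(float) / 255.0
        mono = deshear_stack(linear, demo_result.shift_model)
        residual = estimate_row_shift(mono.data, 80, 8, 119)
        assert abs(residual) <= 1.0

    def test_excessive_slope_rejected(self):
        stack = np.zeros((10, 100, 2, 3))
        with pytest.raises(ValueError):
            deshear_stack(stack, ShiftModel(5.0))


def _mono_from_channel_traces(r, g, b):
    n = len(r)
    data = np.zeros((n, 4, 4, 3))
    data[..., 0] = np.asarray(r)[:, None, None]
    data[..., 1] = np.asarray(g)[:, None, None]
    data[..., 2] = np.asarray(b)[:, None, None]
    return MonoStack(data=data, frame_indices=np.arange(n))


class TestOnsets:
    def test_threshold_crossings_found_by_linear_scan(self):
        # oracle: first/last index above threshold, by direct scan
        n = 300
        f = np.arange(n, dtype=float)
        blue = np.clip((f - 40.3) / 60.0, 0, 1)  # rises through 10% near f=46.3
        red = np.clip((200.7 - f) / 100.0, 0, 1)  # falls through 10% near f=190.7
        mono = _mono_from_channel_traces(red, np.zeros(n), blue)
        grey = np.ones((4, 4), dtype=bool)
        b_on, r_on = detect_onsets(mono, grey, threshold=0.1)
        assert b_on == float(np.nonzero(blue > 0.1 * blue.max())[0][0])
        assert r_on == float(np.nonzero(red > 0.1 * red.max())[0][-1])

    def test_step_rise_at_frame_40(self):
        n = 100
        blue = np.where(np.arange(n) >= 40, 1.0, 0.0)
        red = np.where(np.arange(n) <= 80, 1.0, 0.0)
        mono = _mono_from_channel_traces(red, np.zeros(n), blue)
        b_on, r_on = detect_onsets(mono, np.ones((4, 4), dtype=bool))
        assert (b_on, r_on) == (40.0, 80.0)

    def test_all_zero_trace_errors(self):
        mono = _mono_from_channel_traces(
            np.zeros(50), np.zeros(50), np.zeros(50)
        )
        with pytest.raises(ValueError):
            detect_onsets(mono, np.ones((4, 4), dtype=bool))


class TestWavelengthMap:
    def test_worked_example_onsets_100_306(self):
        wmap = build_wavelength_map((100.0, 306.0))
        assert wmap.m_lambda == pytest.approx(1.0)
        assert wmap.b_lambda == pytest.approx(336.0)
        assert frames_to_wavelength(wmap, 150) == pytest.approx(486.0)

    def test_onsets_at_zero(self):
        wmap = build_wavelength_map((0.0, 206.0))
        assert (wmap.m_lambda, wmap.b_lambda) == (1.0, 436.0)

    def test_anchors_reproduced_exactly(self):
        wmap = build_wavelength_map((37.0, 191.0))
        assert frames_to_wavelength(wmap, 37.0) == 436.0
        assert frames_to_wavelength(wmap, 191.0) == 642.0

    def test_equal_onsets_error(self):
        with pytest.raises(ZeroDivisionError):
            build_wavelength_map((50.0, 50.0))

    def test_negative_dispersion_error(self):
        with pytest.raises(ValueError):
            build_wavelength_map((100.0, 50.0))


class TestTrimAndSum:
    def _mono(self, lam_per_frame):
        wmap = WavelengthMap(1.0, 336.0, 100.0, 306.0)
        frames = np.array([lam - 336.0 for lam in lam_per_frame])
        data = np.ones((len(frames), 2, 2, 3))
        data[..., 0] *= 1.0  # R
        data[..., 1] *= 2.0  # G
        data[..., 2] *= 4.0  # B
        return MonoStack(data=data, frame_indices=frames), wmap

    def test_red_zeroed_outside_window_at_450(self):
        mono, wmap = self._mono([450.0])
        out = trim_and_sum_channels(mono, wmap)
        # 450 nm: blue (430-566) only
        assert np.allclose(out.data, 4.0)

    def test_all_three_channels_active_at_550(self):
        mono, wmap = self._mono([550.0])
        out = trim_and_sum_channels(mono, wmap)
        assert np.allclose(out.data, 1.0 + 2.0 + 4.0)

    def test_green_and_red_only_at_600(self):
        mono, wmap = self._mono([600.0])
        out = trim_and_sum_channels(mono, wmap)
        assert np.allclose(out.data, 1.0 + 2.0)

    def test_zero_stack_stays_zero(self):
        mono, wmap = self._mono([500.0, 550.0])
        mono.data[:] = 0.0
        out = trim_and_sum_channels(mono, wmap)
        assert np.all(out.data == 0.0)

    def test_missing_map_rejected(self):
        mono, _ = self._mono([500.0])
        with pytest.raises(ValueError):
            trim_and_sum_channels(mono, None)


class TestInterpolateBands:
    def _summed(self, lams, values):
        wmap = WavelengthMap(1.0, 0.0, 436.0, 642.0)  # frame number == nm
        data = np.asarray(values, dtype=float)[:, None, None] * np.ones(
            (len(lams), 2, 2)
        )
        return MonoStack(data=data, frame_indices=np.asarray(lams, float)), wmap

    def test_exact_at_knots_and_mean_at_midpoint(self):
        summed, wmap = self._summed([500.0, 510.0], [2.0, 6.0])
        cube = interpolate_bands(summed, wmap, np.array([500.0, 505.0, 510.0]))
        assert np.allclose(cube.values[0, 0], [2.0, 4.0, 6.0])

    def test_default_grid_within_discard_limits(self):
        grid = default_band_grid()
        assert grid.min() >= 435.0 and grid.max() <= 699.0
        assert len(grid) == 225

    def test_uncovered_bands_masked(self):
        summed, wmap = self._summed([500.0, 520.0], [1.0, 1.0])
        cube = interpolate_bands(
            summed, wmap, np.array([490.0, 505.0, 540.0])
        )
        assert not cube.valid_mask[0, 0, 0]
        assert cube.valid_mask[0, 0, 1]
        assert not cube.valid_mask[0, 0, 2]

    def test_grid_outside_limits_rejected(self):
        summed, wmap = self._summed([500.0, 520.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            interpolate_bands(summed, wmap, np.array([400.0, 500.0]))
        with pytest.raises(ValueError):
            interpolate_bands(summed, wmap, np.array([650.0, 720.0]))


class TestEndToEnd:
    def test_wavelength_accuracy_on_monochromatic_target(self, cfg):
        # a narrow reflectance peak must land on the right band
        peak_nm = 560.0
        spec = ag.Spectrum(
            lambda wl: 0.05 + 0.55 * np.exp(-0.5 * ((wl - peak_nm) / 6.0) ** 2),
            "mono",
        )
        scene = ag.make_scene(
            "flat_patch", classes={"mono": spec}, seed=4, rows=64, cols=48
        )
        stack = ag.render_scan(scene, scan=ag.ScanSpec(n_frames=240, seed=4))
        result = ag.build_cube(stack, config=cfg)
        cube = result.cube
        mean = np.nanmean(cube.values[scene.label_map == 1], axis=0)
        band_spacing = np.diff(cube.band_centers).mean()
        recovered = cube.band_centers[np.nanargmax(mean)]
        assert recovered == pytest.approx(peak_nm, abs=band_spacing)

    def test_deshear_idempotent(self, demo_scan, demo_result):
        stack_obj, _ = demo_scan
        linear = stack_obj.counts.astype(float) / 255.0
        mono = deshear_stack(linear, demo_result.shift_model)
        residual = estimate_row_shift(mono.data, 40, 8, 119)
        model2 = fit_shift_model([(111.0, residual)])
        offsets = model2.frame_offset(mono.data.shape[1])
        # the re-estimated shift is below one frame everywhere ...
        assert np.all(np.abs(offsets) <= 1)
        again = deshear_stack(mono.data, model2)
        # ... and re-applying it changes nothing beyond frame rounding:
        # rows whose offset rounds to zero are copied verbatim
        zero_rows = offsets == 0
        assert zero_rows.sum() > mono.data.shape[1] // 2
        assert np.array_equal(
            again.data[:, zero_rows],
            mono.data[again.frame_indices][:, zero_rows],
        )
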