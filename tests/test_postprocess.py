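"""Post-processing: crossings, LAT/APD maps, dispersion, wavefronts,
re-entry classification."""

import numpy as np
import pytest

from fibrosim.grid import GridSpec
from fibrosim.postprocess import (
    ActivationMap,
    ReentryOutcome,
    activation_delay,
    beat_windows_from_events,
    classify_reentry,
    compute_lat_apd,
    detect_active_wavefronts,
    dispersion_stats,
    find_threshold_crossings,
    infarct_region_mask,
)
from fibrosim.solver import VoltageRecording


def make_recording(frames, dt=1.0, events=(), grid=None):
    frames = np.asarray(frames, dtype=np.float32)
    ny, nx = frames.shape[1:]
    grid = grid or GridSpec(nx=nx, ny=ny, dx=0.25)
    return VoltageRecording(
        times=np.arange(frames.shape[0]) * dt,
        frames=frames,
        stim_events=list(events),
        grid=grid,
        metadata={},
    )


class TestThresholdCrossings:
    def test_square_pulse(self):
        t = np.arange(0, 500.0)
        v = np.where((t >= 100) & (t < 350), 0.0, -86.0)
        ups, downs = find_threshold_crossings(t, v)
        assert ups.size == downs.size == 1
        assert 99.0 <= ups[0] <= 100.0
        assert 349.0 <= downs[0] <= 350.0

    def test_never_above_threshold(self):
        t = np.arange(100.0)
        ups, downs = find_threshold_crossings(t, np.full(100, -86.0))
        assert ups.size == 0 and downs.size == 0

    def test_linear_ramp_interpolation(self):
        """Crossing of a ramp is found by exact line intersection."""
        t = np.arange(0, 21.0)
        v = -80.0 + 2.0 * t  # crosses -70 at t = 5.0 between samples
        ups, _ = find_threshold_crossings(t, v)
        assert ups[0] == pytest.approx(5.0)
        t2 = np.array([10.0, 11.0])
        v2 = np.array([-70.8, -69.2])
        ups2, _ = find_threshold_crossings(t2, v2)
        assert 10.0 < ups2[0] < 11.0
        assert ups2[0] == pytest.approx(10.5)


class TestLatApd:
    def test_square_pulse_node(self):
        frames = np.full((500, 2, 2), -86.0)
        frames[100:350, 0, 0] = 0.0
        rec = make_recording(frames)
        (lat, apd), = compute_lat_apd(rec, [(0.0, 500.0)])
        assert lat.values[0, 0] == pytest.approx(100.0, abs=1.0)
        assert apd.values[0, 0] == pytest.approx(250.0, abs=1.0)

    def test_silent_node_gets_sentinel(self):
        frames = np.full((100, 2, 2), -86.0)
        frames[20:60, 0, 0] = 0.0
        rec = make_recording(frames)
        (lat, apd), = compute_lat_apd(rec, [(0.0, 100.0)])
        assert np.isnan(lat.values[1, 0]) and np.isnan(apd.values[1, 0])
        assert np.isfinite(lat.values[0, 0])

    def test_windows_split_beats(self):
        frames = np.full((800, 2, 2), -86.0)
        frames[100:300, 0, 0] = 0.0
        frames[500:700, 0, 0] = 0.0
        rec = make_recording(frames, events=[(95.0, "S1"), (495.0, "S1")])
        windows = beat_windows_from_events(rec.stim_events, 800.0)
        assert windows == [(95.0, 495.0), (495.0, 800.0)]
        maps = compute_lat_apd(rec, windows)
        assert maps[0][0].values[0, 0] == pytest.approx(100.0, abs=1.0)
        assert maps[1][0].values[0, 0] == pytest.approx(500.0, abs=1.0)

    def test_overlapping_windows_rejected(self):
        rec = make_recording(np.full((10, 2, 2), -86.0))
        with pytest.raises(ValueError):
            compute_lat_apd(rec, [(0.0, 5.0), (4.0, 9.0)])

    def test_strip_lat_monotone_with_distance(self, single_s1_strip_recording):
        rec = single_s1_strip_recording
        (lat, apd), = compute_lat_apd(rec, [(0.0, float(rec.times[-1]))])
        mid = rec.grid.ny // 2
        row = lat.values[mid, 12:]
        assert np.all(np.isfinite(row))
        assert np.all(np.diff(row) >= 0)
        assert np.all(apd.values[mid, 12:] > 0)


class TestActivationDelay:
    def test_identical_maps_zero_delay(self):
        m = ActivationMap(np.array([[1.0, 2.0], [3.0, np.nan]]), window=(0, 10))
        d = activation_delay(m, m)
        assert np.allclose(d[:1], 0.0)
        assert np.isnan(d[1, 1])

    def test_window_reference_subtracted(self):
        a = ActivationMap(np.array([[510.0, 512.0]]), window=(500.0, 900.0))
        b = ActivationMap(np.array([[105.0, 107.0]]), window=(100.0, 500.0))
        assert activation_delay(a, b)[0, 0] == pytest.approx(5.0)

    def test_grid_mismatch_rejected(self):
        a = ActivationMap(np.zeros((2, 2)))
        b = ActivationMap(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            activation_delay(a, b)


class TestDispersionStats:
    def test_order_statistics_convention(self):
        """Values 1..100: median 50.5, IQR 49.5, inter-decile 79.2 under
        linear interpolation of order statistics."""
        stats = dispersion_stats(np.arange(1.0, 101.0).reshape(10, 10))
        assert stats["median"] == pytest.approx(50.5)
        assert stats["iqr"] == pytest.approx(49.5)
        assert stats["interdecile"] == pytest.approx(79.2)

    def test_constant_map_zero_spread(self):
        stats = dispersion_stats(np.full((5, 5), 42.0))
        assert stats["iqr"] == 0.0 and stats["interdecile"] == 0.0

    def test_region_mask_restricts(self):
        values = np.arange(100.0).reshape(10, 10)
        mask = values < 10
        stats = dispersion_stats(values, mask)
        assert stats["n"] == 10
        assert stats["median"] == pytest.approx(4.5)

    def test_nan_excluded_and_empty_rejected(self):
        v = np.full((3, 3), np.nan)
        v[0, 0] = 7.0
        assert dispersion_stats(v)["n"] == 1
        with pytest.raises(ValueError):
            dispersion_stats(np.full((2, 2), np.nan))

    def test_infarct_region_mask_union_of_discs(self):
        grid = GridSpec(400, 400, 0.25)
        mask = infarct_region_mask(grid, ((100 / 3, 100 / 3), (200 / 3, 200 / 3)))
        area = mask.sum() * grid.dx**2
        # two discs radius 25 mm minus their overlap; compare to brute force
        assert mask[0, 0] == False  # corner is > 25 mm from both centres
        assert 2000 < area < 2 * np.pi * 25**2


class TestWavefronts:
    def test_resting_sheet_has_none(self):
        frames = np.full((60, 10, 10), -86.0)
        rec = make_recording(frames)
        assert detect_active_wavefronts(rec, 40.0).n_fronts == 0

    def test_planar_band_single_component(self):
        """A wave at speed c leaves an active band of width ~ 20 c."""
        nx, ny, c = 160, 4, 0.5  # 40 mm strip, wave speed in mm/ms
        grid = GridSpec(nx=nx, ny=ny, dx=0.25)
        t = np.arange(0, 60.0)
        x = grid.x_coords()
        frames = np.where(
            x[None, None, :] <= c * t[:, None, None], 0.0, -86.0
        ).astype(np.float32)
        rec = make_recording(frames, grid=grid)
        wf = detect_active_wavefronts(rec, 50.0)
        assert wf.n_fronts == 1
        band_cols = np.unique(np.where(wf.labels > 0)[1])
        width_mm = band_cols.size * grid.dx
        assert width_mm == pytest.approx(20.0 * c, abs=1.0)

    def test_two_separate_pulses_two_components(self):
        frames = np.full((40, 10, 30), -86.0)
        frames[25:, 2:4, 2:5] = 0.0
        frames[25:, 7:9, 20:24] = 0.0
        rec = make_recording(frames)
        assert detect_active_wavefronts(rec, 30.0).n_fronts == 2

    def test_insufficient_coverage_rejected(self):
        rec = make_recording(np.full((10, 2, 2), -86.0))
        with pytest.raises(ValueError):
            detect_active_wavefronts(rec, 5.0)


class TestReentryClassification:
    @pytest.mark.parametrize(
        "early,late,expected",
        [
            (False, False, ReentryOutcome.NONE),
            (True, False, ReentryOutcome.TRANSIENT),
            (False, True, ReentryOutcome.SUSTAINED),
            (True, True, ReentryOutcome.SUSTAINED),
        ],
    )
    def test_truth_table(self, early, late, expected):
        """Exhaustive truth table of the 2.6 s / 3.0 s wavefront rule."""
        frames = np.full((3001, 8, 8), -86.0, dtype=np.float32)
        if early:
            frames[2590:2600, 2:4, 2:4] = 0.0
        if late:
            frames[2990:3000, 5:7, 5:7] = 0.0
        rec = make_recording(frames)
        outcome, n_early, n_late = classify_reentry(rec)
        assert outcome is expected
        assert n_early == int(early) and n_late == int(late)
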