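"""Frame rendering and trace extraction (difference/threshold/superimpose)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phototrace.rasterize import RasterGrid, ellipse_offsets, rasterize_traces
from phototrace.render import FrameStack, RenderConfig, render_frame, render_stack
from phototrace.traces import (difference_threshold, superimpose, trace_series,
                               TraceImage)


def brute_force_ellipse_mask(shape, center_rc, length, width, pixel_size, theta):
    """Independent point-in-ellipse scan over every pixel."""
    a = length / 2.0 / pixel_size
    b = width / 2.0 / pixel_size
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            dx = c - center_rc[1]
            dy = r - center_rc[0]
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            if (u / a) ** 2 + (v / max(b, 0.5)) ** 2 <= 1.0:
                mask[r, c] = True
    return mask


SMALL = RenderConfig(frame_shape=(96, 96), noise_sd=0.0)


class TestRenderFrame:
    def test_zero_cells_is_background_plus_noise(self, rng):
        cfg = RenderConfig(frame_shape=(64, 64), noise_sd=2.0)
        img = render_frame(np.empty((0, 2)), np.empty(0), cfg, rng=rng)
        assert abs(float(img.mean()) - cfg.background_intensity) < 1.0

    @pytest.mark.parametrize("theta", [0.0, 0.7, np.pi / 2, 2.3])
    def test_ellipse_pixel_count_matches_brute_force(self, theta):
        img = render_frame(np.array([[0.0, 0.0]]), np.array([theta]), SMALL)
        got = int((img == SMALL.foreground_intensity).sum())
        grid = SMALL.grid()
        r0, c0 = grid.to_px(np.array([0.0, 0.0]))
        oracle = brute_force_ellipse_mask(SMALL.frame_shape, (int(r0), int(c0)),
                                          SMALL.cell_length, SMALL.cell_width,
                                          SMALL.pixel_size, theta)
        assert got == int(oracle.sum())

    def test_two_distant_cells_are_disjoint_components(self):
        from skimage.measure import label
        cfg = RenderConfig(noise_sd=0.0)
        img = render_frame(np.array([[-500.0, 0.0], [500.0, 0.0]]),
                           np.zeros(2), cfg)
        assert label(img < 130).max() == 2

    def test_translation_equivariance(self):
        # whole-pixel shifts of pixel-centre-aligned cells shift the
        # noise-free image exactly
        px = SMALL.pixel_size
        grid = SMALL.grid()
        p0 = grid.to_um(np.array([44]), np.array([40]))[0]
        a = render_frame(p0[None, :], np.array([0.4]), SMALL)
        b = render_frame((p0 + [5 * px, 3 * px])[None, :], np.array([0.4]), SMALL)
        assert np.array_equal(np.roll(np.roll(a, 3, axis=0), 5, axis=1), b)

    def test_cell_outside_frame_raises_with_id(self):
        with pytest.raises(ValueError, match="cell 7"):
            render_frame(np.array([[5000.0, 0.0]]), np.zeros(1), SMALL,
                         cell_ids=np.array([7]))


class TestRenderStack:
    def _track(self, n_s=10.0, hz=10.0, speed=0.0):
        t = np.arange(0.0, n_s + 1e-9, 1.0 / hz)
        return pd.DataFrame({"cell_id": 0, "t_s": t, "x_um": speed * t,
                             "y_um": 0.0})

    def test_frame_count_contract(self):
        stack = render_stack(self._track(10.0, 10.0), SMALL)
        assert stack.frames.shape[0] == int(np.floor(10.0 * SMALL.frame_rate)) + 1

    def test_round_trip_bit_exact(self, tmp_path):
        stack = render_stack(self._track(2.0, 10.0), SMALL)
        p = tmp_path / "stack.tif"
        stack.save(p)
        back = FrameStack.load(p)
        assert np.array_equal(back.frames, stack.frames)
        assert np.allclose(back.timestamps, stack.timestamps)
        assert back.config == stack.config

    def test_stationary_cell_frames_identical_without_noise(self):
        stack = render_stack(self._track(3.0, 10.0, speed=0.0), SMALL)
        assert np.all(stack.frames == stack.frames[0])

    def test_empty_track_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            render_stack(pd.DataFrame(columns=["cell_id", "t_s", "x_um", "y_um"]),
                         SMALL)


class TestDifferenceThreshold:
    def test_identical_frames_give_empty_binary(self):
        f = np.full((32, 32), 120, dtype=np.uint8)
        assert difference_threshold(f, f, 10).image.sum() == 0

    def test_moving_ellipse_equals_symmetric_difference_oracle(self):
        # displacement larger than the body width: the thresholded difference
        # is exactly the XOR of the two rasterized body masks
        cfg = SMALL
        f1 = render_frame(np.array([[-30.0, 0.0]]), np.zeros(1), cfg)
        f2 = render_frame(np.array([[30.0, 0.0]]), np.zeros(1), cfg)
        got = difference_threshold(f2, f1, 12.0).image
        m1 = f1 < 130
        m2 = f2 < 130
        assert np.array_equal(got, m1 ^ m2)

    def test_pure_noise_below_threshold_mostly_empty(self, rng):
        base = np.full((128, 128), 120.0)
        f1 = (base + rng.normal(0, 2.0, base.shape)).astype(np.uint8)
        f2 = (base + rng.normal(0, 2.0, base.shape)).astype(np.uint8)
        frac = difference_threshold(f2, f1, 8.0).image.mean()
        assert frac < 0.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_threshold(np.zeros((4, 4)), np.zeros((5, 5)), 1.0)


class TestSuperimpose:
    def test_single_frame_is_identity(self, rng):
        img = rng.uniform(size=(16, 16)) > 0.5
        assert np.array_equal(superimpose([img]).image, img)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 6), st.integers(0, 2**32 - 1))
    def test_or_monotone_and_idempotent(self, k, s):
        r = np.random.default_rng(s)
        frames = [r.uniform(size=(12, 12)) > 0.7 for _ in range(k)]
        out = superimpose(frames).image
        # monotone: adding frames never removes foreground
        for f in frames:
            assert np.all(out | f == out)
        # idempotent
        assert np.array_equal(superimpose(frames + frames).image, out)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            superimpose([])


class TestTraceSeries:
    def _stack_of(self, xs, cfg=SMALL):
        frames = np.stack([render_frame(np.array([[x, 0.0]]), np.zeros(1), cfg)
                           for x in xs])
        t = np.arange(len(xs)) / cfg.frame_rate
        return frames, t

    def test_count_depends_only_on_timing(self):
        n = int(np.ceil(13.0 * SMALL.frame_rate)) + 1
        xs = np.zeros(n)
        frames, t = self._stack_of(xs)
        series = trace_series(frames, t, threshold=12.0)
        # 13-s stack: ticks at 3.9 + k/0.77 up to 13 s -> 8 windows
        assert len(series) == 8
        # all-static stack -> every trace empty
        assert all(tr.image.sum() == 0 for tr in series)

    def test_straight_mover_trace_grows_with_window(self):
        cfg = RenderConfig(frame_shape=(160, 160), noise_sd=0.0)
        n = 40
        xs = -120 + 6.5 * np.arange(n)
        frames, t = self._stack_of(xs, cfg)
        areas = []
        for w in (2.6, 3.9, 5.2):
            tr = trace_series(frames, t, window=w, threshold=12.0)[0]
            areas.append(tr.image.sum())
        assert areas[0] < areas[1] < areas[2]

    def test_rotating_cell_trace_is_spotty(self):
        # spinning in place: 3.9-s trace area comparable to one body blob
        cfg = SMALL
        thetas = np.linspace(0, 4 * np.pi, 26)
        frames = np.stack([render_frame(np.array([[0.0, 0.0]]),
                                        np.array([th]), cfg) for th in thetas])
        t = np.arange(26) / cfg.frame_rate
        tr = trace_series(frames, t, threshold=12.0)[0]
        blob = (frames[0] < 130).sum()
        disk = np.pi * (cfg.cell_length / 2 / cfg.pixel_size) ** 2
        assert tr.image.sum() <= 1.2 * disk
        assert tr.image.sum() >= 0.5 * blob

    def test_stack_shorter_than_window_rejected(self):
        frames, t = self._stack_of(np.zeros(4))
        with pytest.raises(ValueError, match="shorter"):
            trace_series(frames, t, window=3.9, threshold=5.0)

    def test_trace_pixels_within_dilated_footprints(self):
        # no spurious foreground on noise-free input
        cfg = SMALL
        xs = -55 + 7.0 * np.arange(14)
        frames, t = self._stack_of(xs, cfg)
        tr = trace_series(frames, t, threshold=12.0)[0]
        union = np.zeros(cfg.frame_shape, dtype=bool)
        for f in frames:
            union |= f < 130
        assert not np.any(tr.image & ~union)


class TestFastPathRasterizer:
    def test_frozen_cells_leave_no_trace(self):
        grid = RasterGrid.for_chamber(pixel_size=6.0)
        pos = np.array([[0.0, 0.0]])
        frames = [(pos, np.zeros(1), np.array([4], dtype=np.int8))] * 5
        img = rasterize_traces(frames, grid)
        assert img.sum() == 0

    def test_moving_cell_footprint_union(self):
        grid = RasterGrid.for_chamber(pixel_size=6.0)
        f = []
        for x in (0.0, 40.0, 80.0):
            f.append((np.array([[x, 0.0]]), np.zeros(1),
                      np.array([3], dtype=np.int8)))
        img = rasterize_traces(f, grid)
        single = rasterize_traces(f[:1], grid)
        assert img.sum() > 2 * single.sum()
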