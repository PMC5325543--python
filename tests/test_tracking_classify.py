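"""Centroid detection, track linking, and motion-type classification."""

import numpy as np
import pytest

from phototrace.classify import (classify_motion, classify_population,
                                 detect_tumbles, swimming_speed, track_features,
                                 label_proportions)
from phototrace.pipeline import make_fixtures
from phototrace.render import RenderConfig, render_frame
from phototrace.simulate import Population, step_population
from phototrace.tracking import Track, detect_centroids, link_tracks, tracks_from_table

from conftest import dark_config, pure_scenario


class TestDetectCentroids:
    def test_empty_frame_gives_empty_list(self):
        cfg = RenderConfig(frame_shape=(64, 64), noise_sd=0.0)
        img = render_frame(np.empty((0, 2)), np.empty(0), cfg)
        assert detect_centroids(img).shape == (0, 2)

    def test_rendered_cell_centroid_within_one_pixel(self):
        cfg = RenderConfig(frame_shape=(96, 96), noise_sd=0.0)
        grid = cfg.grid()
        truth = np.array([12.0, -18.0])
        img = render_frame(truth[None, :], np.array([0.8]), cfg)
        cents = detect_centroids(img, pixel_to_um=grid.to_um)
        assert cents.shape == (1, 2)
        assert np.hypot(*(cents[0] - truth)) <= cfg.pixel_size

    def test_two_distant_cells_two_centroids(self):
        cfg = RenderConfig(noise_sd=0.0)
        img = render_frame(np.array([[-500.0, 0.0], [500.0, 0.0]]),
                           np.zeros(2), cfg)
        assert detect_centroids(img).shape == (2, 2)


class TestLinkTracks:
    def test_single_moving_cell_one_full_track(self):
        t = np.arange(0, 10.0, 0.325)
        cents = [np.array([[100.0 * ti, 0.0]]) for ti in t]
        tracks = link_tracks(cents, t)
        assert len(tracks) == 1
        assert tracks[0].t.size >= 0.95 * t.size

    def test_twenty_separated_cells_no_identity_switches(self, rng):
        # pairwise distance >> v_max * dt: greedy linking is exact
        t = np.arange(0, 6.0, 0.325)
        base = rng.uniform(-1000, 1000, (20, 2))
        base = base[np.argsort(base[:, 0])]
        # spread them on a grid to guarantee separation
        gx, gy = np.meshgrid(np.arange(5), np.arange(4))
        base = np.stack([gx.ravel() * 500.0 - 1000, gy.ravel() * 500.0 - 750], axis=1)
        vel = rng.uniform(-40, 40, (20, 2))
        cents = [base + vel * ti for ti in t]
        tracks = link_tracks(cents, t)
        assert len(tracks) == 20
        for k, tr in enumerate(tracks):
            assert tr.t.size == t.size
            # each track stays with its starting cell
            assert np.allclose(tr.xy[0], cents[0][k])
            assert np.allclose(tr.xy[-1], cents[-1][k])

    def test_empty_stream_empty_tracks(self):
        assert link_tracks([np.empty((0, 2))] * 5, np.arange(5.0)) == []

    def test_crossing_pair_fixture_min_separation(self):
        fx = make_fixtures("crossing_pair")
        a = fx[fx.cell_id == 0][["x_um", "y_um"]].to_numpy()
        b = fx[fx.cell_id == 1][["x_um", "y_um"]].to_numpy()
        assert np.min(np.hypot(*(a - b).T)) < 35.0


class TestTumbles:
    def test_straight_noiseless_track_no_events(self):
        t = np.arange(0, 32, 0.325)
        tr = Track(0, t, np.stack([100 * t, np.zeros_like(t)], axis=1))
        assert detect_tumbles(tr) == []

    def test_four_sharp_turns_detected(self):
        fx = make_fixtures("single_cell_each_mode")
        g = fx[fx["mode"] == "run_tumble"]
        tr = Track(0, g["t_s"].to_numpy(), g[["x_um", "y_um"]].to_numpy())
        assert len(detect_tumbles(tr)) == 4

    def test_sampling_coarser_than_window_rejected(self):
        t = np.arange(0, 32, 4.0)
        tr = Track(0, t, np.stack([10 * t, t], axis=1))
        with pytest.raises(ValueError, match="coarser"):
            detect_tumbles(tr)


class TestClassification:
    def test_fixture_types_recovered(self):
        fx = make_fixtures("single_cell_each_mode")
        for tr in tracks_from_table(fx):
            name = fx[fx.cell_id == tr.cell_id]["mode"].iloc[0]
            f = track_features(tr)
            assert classify_motion(f) == name

    def test_large_circle_is_circular(self):
        t = np.arange(0, 32, 0.325)
        omega = 140.0 / 300.0
        xy = 300.0 * np.stack([np.cos(omega * t), np.sin(omega * t)], axis=1)
        f = track_features(Track(0, t, xy))
        assert classify_motion(f) == "circular"

    def test_stationary_cell_excluded(self):
        t = np.arange(0, 32, 0.325)
        f = track_features(Track(0, t, np.zeros((t.size, 2))))
        assert classify_motion(f) == "irregular_excluded"

    def test_simulated_cohort_recall(self):
        # per-type recall >= 95% on ground-truth tracks of pure cohorts:
        # 4 s of dark then a 32-s light step-up, as in a real pulse
        for tidx, name in [(0, "rotation"), (1, "run_tumble"),
                           (2, "circular"), (3, "straight")]:
            n = 150
            # keep circles well inside: arcs broken at the wall are no
            # longer circles for any observer
            band = (150.0, 300.0) if tidx == 2 else (150.0, 600.0)
            cfg = dark_config(n_cells=n, seed=40 + tidx,
                              scenario=pure_scenario(tidx),
                              circle_radius_band=band)
            r = np.random.default_rng(cfg.seed)
            pop = Population.initial(cfg, r)
            pop.pos *= 0.4 if tidx != 2 else 0.2  # sample away from the wall
            if tidx >= 2:
                pop.v0[:] = r.uniform(120, 180, n)  # adapted fast speeds
            samples, times = [], []
            for k in range(int(36.0 / cfg.dt) + 1):
                t = k * cfg.dt
                if k % 4 == 0:
                    times.append(t)
                    samples.append(pop.pos.copy())
                on = np.full(n, t >= 4.0)
                step_population(pop, t, cfg, r, light_on=on)
            arr = np.array(samples)
            tracks = [Track(i, np.array(times), arr[:, i, :]) for i in range(n)]
            labels = classify_population(tracks, (4.0, 36.0))
            ok = labels[labels.label != "irregular_excluded"]
            recall = np.mean(ok["label"] == name)
            assert recall >= 0.95, f"{name}: recall {recall:.3f}"

    def test_label_proportions_ignore_excluded(self):
        import pandas as pd
        df = pd.DataFrame({"cell_id": range(4),
                           "label": ["rotation", "rotation", "straight",
                                     "irregular_excluded"],
                           "mean_speed": 1.0, "tumble_count": 0,
                           "gyration_radius": 1.0})
        p = label_proportions(df)
        assert p["rotation"] == pytest.approx(2 / 3)


class TestSwimmingSpeed:
    def test_constant_speed_track(self):
        t = np.arange(0, 10, 0.325)
        tr = Track(0, t, np.stack([100 * t, np.zeros_like(t)], axis=1))
        assert swimming_speed(tr) == pytest.approx(100.0, abs=1e-9)

    def test_stationary_zero(self):
        t = np.arange(0, 10, 0.325)
        assert swimming_speed(Track(0, t, np.zeros((t.size, 2)))) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            swimming_speed(Track(0, [0.0, 1.0], [[0, 0], [1, 1]]), (0.0, 0.0))

    def test_cycle1_population_speed_range(self):
        # initial draws 50-140 um/s: dark-swimming measured speeds within
        # [45, 150] (rotational diffusion only shortens paths slightly)
        from phototrace.simulate import run_simulation
        cfg = dark_config(n_cells=60, duration=30.0, seed=11)
        tracks = tracks_from_table(run_simulation(cfg))
        v = [swimming_speed(tr) for tr in tracks]
        assert min(v) >= 45.0 and max(v) <= 150.0
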