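"""Simulator kinematics, mode transitions, and population invariants."""

import numpy as np
import pytest

from phototrace.protocol import Schedule, dark, expA
from phototrace.scenario import MotionType, SCENARIOS
from phototrace.simulate import (Population, SimulationConfig, run_simulation,
                                 step_population)

from conftest import dark_config, pure_scenario


def force_mode(pop: Population, mode: MotionType) -> None:
    pop.mode[:] = int(mode)
    pop.anchor[:] = pop.pos
    pop.anchor0[:] = pop.pos


class TestKinematics:
    def test_straight_displacement_is_speed_times_dt(self, rng):
        cfg = dark_config(n_cells=1, heading_diffusion=0.0)
        pop = Population.initial(cfg, rng)
        pop.pos[:] = 0.0
        pop.heading[:] = 0.0
        pop.v0[:] = 100.0
        start = pop.pos.copy()
        step_population(pop, 0.0, cfg, rng, light_on=np.array([False]))
        assert pop.pos[0, 0] - start[0, 0] == pytest.approx(100.0 * cfg.dt)
        assert pop.pos[0, 1] == pytest.approx(0.0)

    def test_rotation_stays_within_confinement_radius_over_pulse(self, rng):
        cfg = dark_config(n_cells=50, scenario=pure_scenario(0))
        pop = Population.initial(cfg, rng)
        pop.pos *= 0.5  # keep clear of the wall
        force_mode(pop, MotionType.ROTATION)
        start = pop.pos.copy()
        on = np.ones(50, dtype=bool)
        for k in range(int(32.0 / cfg.dt)):
            step_population(pop, k * cfg.dt, cfg, rng, light_on=on)
        net = np.hypot(*(pop.pos - start).T)
        assert np.all(net <= cfg.rot_confine + 1e-6)

    def test_rotation_trace_footprint_is_spotty(self, rng):
        # over a 3.9-s trace window the rotating cell's centroid stays
        # within its gyration circle plus a few um of anchor jitter
        cfg = dark_config(n_cells=200, scenario=pure_scenario(0))
        pop = Population.initial(cfg, rng)
        pop.pos *= 0.5
        force_mode(pop, MotionType.ROTATION)
        start = pop.pos.copy()
        on = np.ones(200, dtype=bool)
        for k in range(int(3.9 / cfg.dt)):
            step_population(pop, k * cfg.dt, cfg, rng, light_on=on)
        rms = np.sqrt(np.mean(np.sum((pop.pos - start) ** 2, axis=1)))
        assert rms < 2.0 * cfg.rot_wobble

    def test_run_tumble_count_in_paper_band(self, rng):
        # Poisson tumbling at 0.125 /s: mean reorientations over a 32-s
        # pulse land in the observed 3-5 range
        n = 1000
        cfg = dark_config(n_cells=n, scenario=pure_scenario(1),
                          heading_diffusion=0.0)
        pop = Population.initial(cfg, rng)
        pop.pos *= 0.05  # far from the wall: no reflections
        force_mode(pop, MotionType.RUN_TUMBLE)
        pop.v0[:] = 1.0  # slow: stay clear of the wall for 32 s
        on = np.ones(n, dtype=bool)
        counts = np.zeros(n)
        for k in range(int(32.0 / cfg.dt)):
            before = pop.heading.copy()
            step_population(pop, k * cfg.dt, cfg, rng, light_on=on)
            counts += pop.heading != before
        assert 3.0 <= counts.mean() <= 5.0

    def test_circular_mode_turns_at_speed_over_radius(self, rng):
        cfg = dark_config(n_cells=1, scenario=pure_scenario(2),
                          heading_diffusion=0.0)
        pop = Population.initial(cfg, rng)
        pop.pos[:] = 0.0
        pop.heading[:] = 0.0
        pop.v0[:] = 120.0
        force_mode(pop, MotionType.CIRCULAR)
        pop.circ_radius[:] = 300.0
        pop.circ_sign[:] = 1.0
        h0 = pop.heading[0]
        step_population(pop, 0.0, cfg, rng, light_on=np.array([True]))
        assert pop.heading[0] - h0 == pytest.approx(120.0 / 300.0 * cfg.dt)


class TestTransitions:
    def test_latency_bounds_mode_entry_after_step_up(self, rng):
        cfg = dark_config(n_cells=300, scenario=pure_scenario(0))
        pop = Population.initial(cfg, rng)
        pop.pos *= 0.5
        on = np.ones(300, dtype=bool)
        t, entered_by = 0.0, None
        for k in range(int(1.0 / cfg.dt)):
            step_population(pop, k * cfg.dt, cfg, rng, light_on=on)
            t = (k + 1) * cfg.dt
            if np.all(pop.mode == int(MotionType.ROTATION)):
                entered_by = t
                break
        assert entered_by is not None
        assert entered_by <= cfg.latency[1] + 2 * cfg.dt

    def test_no_photophobic_modes_in_permanent_dark(self, rng):
        cfg = dark_config(n_cells=100, duration=120.0, seed=7)
        tracks = run_simulation(cfg)
        assert set(tracks["mode"].unique()) <= {"straight"}

    def test_step_down_freezes_then_resumes_straight(self, rng):
        cfg = dark_config(n_cells=1, scenario=pure_scenario(0))
        pop = Population.initial(cfg, rng)
        pop.pos[:] = 0.0
        force_mode(pop, MotionType.ROTATION)
        step_population(pop, 0.0, cfg, rng, light_on=np.array([False]))
        assert pop.mode[0] == int(MotionType.FROZEN)
        frozen_pos = pop.pos.copy()
        n_frozen_steps = int(np.ceil(cfg.freeze_duration / cfg.dt))
        for k in range(n_frozen_steps):
            step_population(pop, (k + 1) * cfg.dt, cfg, rng,
                            light_on=np.array([False]))
        assert np.allclose(pop.pos, frozen_pos)  # no displacement while frozen
        step_population(pop, 0.0, cfg, rng, light_on=np.array([False]))
        assert pop.mode[0] == int(MotionType.STRAIGHT)

    def test_tolerant_cells_ignore_light(self, rng):
        cfg = dark_config(n_cells=20, scenario=pure_scenario(3))
        pop = Population.initial(cfg, rng)
        on = np.ones(20, dtype=bool)
        for k in range(50):
            step_population(pop, k * cfg.dt, cfg, rng, light_on=on)
        assert np.all(pop.mode == int(MotionType.STRAIGHT))

    def test_activity_scale_stops_cells_below_threshold(self, rng):
        cfg = dark_config(n_cells=10, activity_scale=0.1)
        pop = Population.initial(cfg, rng)
        assert np.all(pop.mode == int(MotionType.STOPPED))
        p0 = pop.pos.copy()
        step_population(pop, 0.0, cfg, rng, light_on=np.zeros(10, bool))
        assert np.allclose(pop.pos, p0)


class TestRunSimulation:
    def test_validation(self):
        with pytest.raises(ValueError):
            dark_config(n_cells=0)
        with pytest.raises(ValueError):
            dark_config(dt=0.6)
        with pytest.raises(ValueError):
            dark_config(dt=-0.1)

    def test_conservation_and_confinement(self):
        cfg = dark_config(n_cells=25, duration=60.0, seed=3)
        tracks = run_simulation(cfg)
        geo = cfg.geometry
        for t, g in tracks.groupby("t_s"):
            assert len(g) == 25
            r = np.hypot(g["x_um"], g["y_um"])
            assert np.all(r < geo.radius)
        assert tracks.groupby("cell_id")["t_s"].apply(
            lambda s: np.all(np.diff(s) > 0)).all()

    def test_seeded_determinism_bit_identical(self):
        cfg = SimulationConfig(schedule=Schedule(((expA(), 1),)), n_cells=15,
                               seed=42, scenario=SCENARIOS["standard"])
        a = run_simulation(cfg, duration=120.0)
        b = run_simulation(cfg, duration=120.0)
        assert a.equals(b)

    def test_single_cell_dark_monotone_track(self):
        cfg = dark_config(n_cells=1, duration=30.0)
        tr = run_simulation(cfg)
        assert tr["cell_id"].nunique() == 1
        assert np.all(np.diff(tr["t_s"]) > 0)
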