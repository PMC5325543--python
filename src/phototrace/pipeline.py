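"""End-to-end protocol runner and fixture generation.

The runner streams the simulation through the stimulation schedule and
computes trace-momentum series on the fly (the *fast path*: trace images are
rasterized directly from simulated states instead of rendering video, which
is equivalent up to the difference-imaging approximation and is validated
against the full render -> extract chain on small windows).  Frame timing is
locked to the trace clock: 3.08 fps frames (four simulation steps each),
trace refresh every fourth frame (0.77 Hz), 3.9-s superimposition windows.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .adaptation import CycleSeries, assemble_cycles, fit_cycle_series
from .classify import classify_population, label_proportions
from .geometry import ChamberGeometry, area_masks
from .metrics import decrease_ratio, separation_ratio, area_occupancy
from .protocol import (Schedule, LightProtocol, expA, expB, cycleAB,
                       SEGMENT_DURATION_S, CYCLE_DURATION_S)
from .rasterize import RasterGrid, TraceRasterizer
from .render import RenderConfig, FrameStack, render_frame
from .scenario import SCENARIOS, AdaptationScenario
from .simulate import SimulationConfig, iter_simulation
from .tracking import Track

FRAME_RATE = 3.08
STEPS_PER_FRAME = 4
SIM_DT = 1.0 / (FRAME_RATE * STEPS_PER_FRAME)
FRAMES_PER_REFRESH = 4          # 0.77-Hz refresh
WINDOW_FRAMES = 13              # raw frames per 3.9-s window (12 differences)
WINDOW_S = 3.9


@dataclass
class CollectionPlan:
    """What to collect while streaming a schedule."""

    tm_spans: list[tuple[float, float]] = field(default_factory=list)
    track_spans: list[tuple[float, float]] = field(default_factory=list)
    snapshot_times: list[float] = field(default_factory=list)


@dataclass
class StreamResult:
    tm: pd.DataFrame
    track_times: np.ndarray        # (F,)
    track_pos: np.ndarray          # (F, n, 2)
    track_mode: np.ndarray         # (F, n)
    snapshots: list[tuple[float, np.ndarray]]

    def tracks(self, span: tuple[float, float] | None = None) -> list[Track]:
        """Ground-truth Track objects from the collected frame samples."""
        t = self.track_times
        sel = np.ones(t.shape, dtype=bool) if span is None else \
            (t >= span[0] - 1e-9) & (t <= span[1] + 1e-9)
        tt = t[sel]
        pp = self.track_pos[sel]
        return [Track(i, tt, pp[:, i, :], source="ground_truth")
                for i in range(pp.shape[1])]


def _in_any(t: float, spans: list[tuple[float, float]], pad: float = 0.0) -> bool:
    return any(a - pad - 1e-9 <= t <= b + 1e-9 for a, b in spans)


def stream_protocol(config: SimulationConfig, plan: CollectionPlan,
                    grid: RasterGrid | None = None,
                    cell_length: float | None = None,
                    cell_width: float | None = None,
                    duration: float | None = None) -> StreamResult:
    """Run the schedule, computing TM windows and track samples per plan.

    ``duration`` truncates the run (metrics whose windows lie beyond it are
    simply absent).
    """
    rc = RenderConfig()
    grid = grid or RasterGrid.for_chamber(config.geometry, rc.pixel_size)
    rast = TraceRasterizer(grid, cell_length or rc.cell_length,
                           cell_width or rc.cell_width)
    masks = area_masks(grid.shape, grid.pixel_size, config.geometry,
                       frame_origin=grid.origin)
    m_whole = masks["whole"].ravel()
    m_i = masks["area_I"].ravel()
    m_ii = masks["area_II"].ravel()

    frame_buf: list[tuple[float, np.ndarray, np.ndarray, np.ndarray]] = []
    tm_rows = []
    trk_t, trk_pos, trk_mode = [], [], []
    snap_times = sorted(plan.snapshot_times)
    snaps: list[tuple[float, np.ndarray]] = []
    si = 0
    frame_idx = -1
    npix = grid.shape[0] * grid.shape[1]
    img = np.zeros(npix, dtype=bool)

    for k, t, pop in iter_simulation(config, duration=duration):
        while si < len(snap_times) and t >= snap_times[si] - config.dt / 2:
            snaps.append((t, pop.pos.copy()))
            si += 1
        if k % STEPS_PER_FRAME:
            continue
        frame_idx += 1
        need_tm = _in_any(t, plan.tm_spans, pad=WINDOW_S)
        need_trk = _in_any(t, plan.track_spans)
        if need_tm or need_trk:
            state = (t, pop.pos.copy(), pop.heading.copy(), pop.mode.copy())
        if need_trk:
            trk_t.append(t)
            trk_pos.append(state[1])
            trk_mode.append(state[3])
        if need_tm:
            frame_buf.append(state)
            if len(frame_buf) > WINDOW_FRAMES:
                frame_buf.pop(0)
        else:
            frame_buf.clear()
        if (frame_idx % FRAMES_PER_REFRESH == 0
                and len(frame_buf) == WINDOW_FRAMES):
            t_end = frame_buf[-1][0]
            t_start = t_end - WINDOW_S
            if _in_any(t_start, plan.tm_spans) and _in_any(t_end, plan.tm_spans):
                img[:] = False
                for _, p, h, m in frame_buf:
                    rast.stamp_frame(img, p, h, m)
                tm_rows.append((t_start, t_end,
                                int(np.count_nonzero(img[m_whole])),
                                int(np.count_nonzero(img[m_i])),
                                int(np.count_nonzero(img[m_ii])),
                                frame_idx // FRAMES_PER_REFRESH))
    tm = pd.DataFrame(tm_rows, columns=["window_start", "t_s", "tm_whole",
                                        "tm_I", "tm_II", "refresh_index"])
    return StreamResult(
        tm=tm,
        track_times=np.array(trk_t),
        track_pos=np.array(trk_pos) if trk_pos else np.empty((0, config.n_cells, 2)),
        track_mode=np.array(trk_mode) if trk_mode else np.empty((0, config.n_cells)),
        snapshots=snaps,
    )


# ------------------------------------------------------- segment conveniences


def segment_start(cycle: int, kind: str,
                  cycle_duration: float = CYCLE_DURATION_S) -> float:
    """Absolute start time (s) of experiment ``kind`` in 1-based ``cycle``."""
    base = (cycle - 1) * cycle_duration
    return base if kind == "A" else base + SEGMENT_DURATION_S


def pulse_span(proto: LightProtocol, pulses: tuple[int, int],
               seg_start: float = 0.0, guard_pad: float = 4.0) -> tuple[float, float]:
    """Span covering on/off phases of a 1-based pulse range (inclusive)."""
    a0, _ = proto.pulse_window(pulses[0])
    _, b1 = proto.pulse_window(pulses[1])
    return (seg_start + a0 - proto.pulse_off,
            seg_start + b1 + proto.pulse_off + guard_pad)


def make_segment_config(kind: str, cycle: int = 1, n_cells: int = 100,
                        seed: int = 0, scenario: str | AdaptationScenario = "standard",
                        activity_scale: float = 1.0, **kw) -> SimulationConfig:
    """Config for a standalone A or B segment at its in-protocol clock time.

    The preceding dark padding of the full protocol redistributes cells, so a
    standalone segment starts from a uniform population with the adaptation
    clock set to the segment's position in the protocol.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    proto = expA() if kind == "A" else expB()
    return SimulationConfig(
        schedule=Schedule(((proto, 1),)), n_cells=n_cells, seed=seed,
        scenario=scenario, dt=SIM_DT, activity_scale=activity_scale,
        start_elapsed_s=segment_start(cycle, kind), **kw)


def run_experiment(kind: str, cycle: int = 1, n_cells: int = 100, seed: int = 0,
                   scenario: str | AdaptationScenario = "standard",
                   decrease_pulse: int = 4, classify_pulse: int | None = None,
                   snapshot_at_board_end: bool = False,
                   activity_scale: float = 1.0,
                   duration: float | None = None, **kw) -> dict:
    """Simulate one standalone experiment segment and compute its metrics.

    Returns a dict with the TM series and, per ``kind``: the decrease ratio
    (A), classified labels / type proportions (A, if ``classify_pulse``), or
    separation ratios and optional end-of-board occupancy (B).
    """
    config = make_segment_config(kind, cycle, n_cells, seed, scenario,
                                 activity_scale, **kw)
    proto = config.schedule.segments[0][0]
    plan = CollectionPlan()
    if kind == "A":
        plan.tm_spans = [pulse_span(proto, (decrease_pulse - 1, decrease_pulse))]
        if classify_pulse is not None:
            on0, on1 = proto.pulse_window(classify_pulse)
            # extra lead-in: tumble detection looks back before the pulse
            plan.track_spans = [(on0 - 4.0, on1)]
            plan.tm_spans.append((on0 - WINDOW_S, on1))
    else:
        plan.tm_spans = [(0.0, proto.segment_duration)]
        if snapshot_at_board_end:
            plan.snapshot_times = [proto.board_duration]
    res = stream_protocol(config, plan, duration=duration)
    out: dict = {"config": config, "tm": res.tm, "stream": res}
    if kind == "A":
        out["decrease"] = decrease_ratio(res.tm, proto, pulse_index=decrease_pulse)
        if classify_pulse is not None:
            on = proto.pulse_window(classify_pulse)
            labels = classify_population(res.tracks(on), on)
            out["labels"] = labels
            out["proportions"] = label_proportions(labels)
    else:
        out["separation"] = separation_ratio(res.tm, proto)
        if snapshot_at_board_end:
            t, pos = res.snapshots[0]
            out["occupancy_I"] = area_occupancy(pos, config.geometry,
                                                square=proto.board_square)
    return out


# ----------------------------------------------------------- full protocol


@dataclass
class RunManifest:
    """Provenance record of one protocol run."""

    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, status: str, elapsed: float, outputs: list[str]) -> None:
        self.stages.append({"stage": name, "status": status,
                            "elapsed_s": round(elapsed, 3), "outputs": outputs})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def config_hash(obj) -> str:
    """Stable hash of a (nested) config mapping; key order independent."""
    def default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items() if not k.startswith("_")}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_protocol(n_cycles: int = 8, n_cells: int = 100, seed: int = 0,
                 scenario: str | AdaptationScenario = "standard",
                 decrease_pulse: int = 4, proportions_pulse: int = 3,
                 classify: bool = True, collect_separation: bool = True,
                 activity_scale: float = 1.0,
                 out_dir: str | Path | None = None) -> dict:
    """Run the alternating AB protocol end to end (fast path).

    Per cycle this measures the decrease ratio at ``decrease_pulse`` of A,
    motion-type proportions at ``proportions_pulse`` of A (classifier on
    ground-truth tracks), and the B separation ratios; then fits the
    adaptation time constant to the decrease-ratio and separation series.

    Returns a dict with ``cycles`` (CycleSeries), ``fit_decrease``,
    ``fit_separation``, ``tm``, ``labels`` and ``manifest``; artifacts are
    written to ``out_dir`` when given.
    """
    from . import __version__

    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    t_wall = _time.perf_counter()
    config = SimulationConfig(schedule=cycleAB(n_cycles), n_cells=n_cells,
                              seed=seed, scenario=scenario, dt=SIM_DT,
                              activity_scale=activity_scale)
    protoA, protoB = expA(), expB()
    plan = CollectionPlan()
    class_windows = []
    for c in range(1, n_cycles + 1):
        a0 = segment_start(c, "A")
        plan.tm_spans.append(pulse_span(protoA, (decrease_pulse - 1, decrease_pulse), a0))
        if classify:
            on0, on1 = protoA.pulse_window(proportions_pulse)
            w = (a0 + on0, a0 + on1)
            class_windows.append(w)
            plan.track_spans.append((w[0] - 4.0, w[1]))
        if collect_separation:
            b0 = segment_start(c, "B")
            plan.tm_spans.append((b0, b0 + protoB.segment_duration))
    manifest = RunManifest(
        config_hash=config_hash({
            "n_cycles": n_cycles, "n_cells": n_cells, "seed": seed,
            "scenario": scenario, "decrease_pulse": decrease_pulse,
            "proportions_pulse": proportions_pulse,
            "activity_scale": activity_scale}),
        seed=seed, version=__version__)

    t0 = _time.perf_counter()
    res = stream_protocol(config, plan)
    manifest.add("simulate+extract+tm", "ok", _time.perf_counter() - t0,
                 ["tm_series"])

    t0 = _time.perf_counter()
    per_cycle, labels_all = [], []
    for c in range(1, n_cycles + 1):
        rec: dict = {"cycle": c}
        a0 = segment_start(c, "A")
        rec["decrease_ratio"] = decrease_ratio(
            res.tm, protoA, pulse_index=decrease_pulse, segment_start=a0).value
        if collect_separation:
            sep = separation_ratio(res.tm, protoB, segment_start=segment_start(c, "B"))
            rec["separation_on"] = sep.s_on
            rec["separation_off"] = sep.s_off
        if classify:
            w = class_windows[c - 1]
            lab = classify_population(res.tracks(w), w)
            lab.insert(0, "cycle", c)
            labels_all.append(lab)
            props = label_proportions(lab)
            rec.update({f"p_{k}": float(v) for k, v in props.items()})
        per_cycle.append(rec)
    cycles = assemble_cycles(per_cycle)
    fit_d = fit_cycle_series(cycles, "decrease_ratio") if n_cycles >= 3 else None
    fit_s = None
    if collect_separation and n_cycles >= 3:
        try:
            fit_s = fit_cycle_series(cycles, "separation_on")
        except ValueError:
            fit_s = None
    manifest.add("metrics+classify+fit", "ok", _time.perf_counter() - t0,
                 ["cycles", "fit"])
    manifest.add("total", "ok", _time.perf_counter() - t_wall, [])

    out = {"config": config, "cycles": cycles, "tm": res.tm,
           "labels": pd.concat(labels_all, ignore_index=True) if labels_all else None,
           "fit_decrease": fit_d, "fit_separation": fit_s, "manifest": manifest}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cycles.table.to_csv(out_dir / "cycles.csv", index=False)
        res.tm.to_csv(out_dir / "tm_series.csv", index=False)
        if out["labels"] is not None:
            out["labels"].to_csv(out_dir / "labels.csv", index=False)
        fits = {}
        for name, f in (("decrease", fit_d), ("separation_on", fit_s)):
            if f is not None:
                fits[name] = {"amplitude": f.amplitude, "offset": f.offset,
                              "tau_h": f.tau, "rss": f.rss, "converged": f.converged}
        (out_dir / "fit.json").write_text(json.dumps(fits, indent=2))
        (out_dir / "manifest.json").write_text(manifest.to_json())
    return out


# ------------------------------------------------------------- full path


def render_span(config: SimulationConfig, span: tuple[float, float],
                render_config: RenderConfig | None = None,
                noise_seed: int | None = None) -> FrameStack:
    """Simulate and render video frames for a time span (full path)."""
    rc = render_config or RenderConfig()
    rng_noise = np.random.default_rng(config.seed + 1 if noise_seed is None
                                      else noise_seed)
    frames, times = [], []
    for k, t, pop in iter_simulation(config, duration=span[1]):
        if k % STEPS_PER_FRAME:
            continue
        if t < span[0] - 1e-9:
            continue
        frames.append(render_frame(pop.pos, pop.heading, rc, rng=rng_noise))
        times.append(t)
    return FrameStack(frames=np.array(frames), timestamps=np.array(times),
                      config=rc)


def measure_switch_latency(seed: int = 0, step_up_at: float = 20.0,
                           duration: float = 60.0,
                           window_s: float = WINDOW_S,
                           r_rot: float = 40.0) -> float:
    """Detected straight-to-rotation switch delay from a rendered video.

    A single rotation-type cell swims in the dark until a uniform blue-light
    step-up at ``step_up_at``; frames are rendered with noise, centroids are
    detected and linked, and the switch is located as the start of the first
    sliding track window (``window_s`` long, stepped at frame resolution)
    whose gyration radius falls below the on-site-rotation threshold.
    Returns detected switch time minus step-up time (s).
    """
    from .protocol import Schedule, LightProtocol, dark
    from .tracking import detect_centroids, link_tracks

    on_len = duration - step_up_at
    proto = LightProtocol(kind="uniform_pulses", pulse_on=on_len - 1.0,
                          pulse_off=1.0, n_pulses=1, segment_duration=on_len)
    sched = Schedule(((dark(step_up_at), 1), (proto, 1)))
    # a pure rotation-type cell: the probe measures the step-up latency of
    # the classic on-site-rotation response
    scenario = AdaptationScenario(name="rotation_probe", p0=(1, 0, 0, 0),
                                  p_inf=(1, 0, 0, 0))
    cfg = SimulationConfig(schedule=sched, n_cells=1, seed=seed, dt=SIM_DT,
                           scenario=scenario)
    stack = render_span(cfg, (0.0, duration))
    grid = stack.config.grid()
    cents = [detect_centroids(f, pixel_to_um=grid.to_um) for f in stack.frames]
    tracks = link_tracks(cents, stack.timestamps)
    track = max(tracks, key=lambda tr: tr.t.size)
    t = track.t
    for i in range(t.size):
        if t[i] + window_s > t[-1] + 1e-9:
            break
        sub = track.window(t[i], t[i] + window_s)
        if sub.t.size < 3:
            continue
        centred = sub.xy - sub.xy.mean(axis=0)
        gyr = float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))
        # a qualifying window is pure rotation: confined AND without any
        # straight run inside (large frame-to-frame hops)
        hops = np.hypot(*np.diff(sub.xy, axis=0).T)
        if gyr < r_rot and hops.max() < 20.0:
            return float(t[i] - step_up_at)
    return float("inf")


# --------------------------------------------------------------- fixtures


FIXTURE_KINDS = ("single_cell_each_mode", "crossing_pair",
                 "checkerboard_small", "cycle1_minipop")


def make_fixtures(kind: str, seed: int = 0):
    """Small deterministic inputs for tests and examples."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / FRAME_RATE
    t = np.arange(0.0, 32.0 + 1e-9, dt)
    if kind == "single_cell_each_mode":
        rows = []
        # rotation: confined jitter walk
        xy = np.cumsum(rng.normal(0, 2.0, (t.size, 2)), axis=0)
        xy -= xy.mean(axis=0)
        rows.append(("rotation", xy))
        # run/tumble: straight runs with 4 sharp turns (>= 60 deg each)
        run_headings = np.array([0.3, 1.9, 3.6, 5.2, 0.6])
        heads = np.repeat(run_headings, int(np.ceil(t.size / 5)))[:t.size]
        steps = 80.0 * dt * np.stack([np.cos(heads), np.sin(heads)], axis=1)
        rows.append(("run_tumble", np.cumsum(steps, axis=0) - 400.0))
        # circular: 600-um diameter circle at 140 um/s
        r = 300.0
        omega = 140.0 / r
        rows.append(("circular", np.stack([r * np.cos(omega * t), r * np.sin(omega * t)],
                                          axis=1)))
        # straight at 100 um/s
        rows.append(("straight", np.stack([-900 + 100.0 * t, np.full(t.size, 600.0)],
                                          axis=1)))
        frames = []
        for cid, (name, xy) in enumerate(rows):
            frames.append(pd.DataFrame({"cell_id": cid, "t_s": t, "x_um": xy[:, 0],
                                        "y_um": xy[:, 1], "mode": name,
                                        "speed_um_s": np.nan}))
        return pd.concat(frames, ignore_index=True)
    if kind == "crossing_pair":
        a = np.stack([-500 + 100.0 * t, np.zeros(t.size)], axis=1)
        b = np.stack([np.zeros(t.size), -500 + 100.0 * t], axis=1)
        return pd.concat([
            pd.DataFrame({"cell_id": 0, "t_s": t, "x_um": a[:, 0], "y_um": a[:, 1],
                          "mode": "straight", "speed_um_s": 100.0}),
            pd.DataFrame({"cell_id": 1, "t_s": t, "x_um": b[:, 0], "y_um": b[:, 1],
                          "mode": "straight", "speed_um_s": 100.0}),
        ], ignore_index=True)
    if kind == "checkerboard_small":
        geo = ChamberGeometry()
        grid = RasterGrid.for_chamber(geo, pixel_size=6.0, margin_px=4)
        masks = area_masks(grid.shape, grid.pixel_size, geo, frame_origin=grid.origin)
        return {"grid": grid, "masks": masks}
    if kind == "cycle1_minipop":
        cfg = make_segment_config("A", cycle=1, n_cells=20, seed=seed)
        from .simulate import run_simulation
        return run_simulation(cfg, duration=160.0)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
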