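"""Agent-based 2-D simulator of photophobic swimming in a circular chamber.

Model summary
-------------
Each cell swims in the chamber plane with a per-cell speed and heading.  In
the dark every motile cell swims straight (with slow rotational diffusion of
the heading).  When blue light is on at a cell's position, the cell expresses
its photophobic *type* after a short latency:

* ``rotation``   -- the cell spins on-site; its position performs a small
  jittery walk (diffusion ``rot_diffusion``) reflected inside a confinement
  disk around the capture point, so traces stay spot-like;
* ``run_tumble`` -- an immediate avoidance reversal (heading + pi +/- jitter)
  followed by straight runs interrupted by Poisson tumbles
  (``tumble_rate_in_light``, uniform reorientation);
* ``circular``   -- swimming along a large circle (diameter 300-1200 um);
* ``straight``   -- no response (blue-light tolerant).

At light step-down any cell in a photophobic mode freezes for
``freeze_duration`` and then resumes straight swimming.  The population's
type mixture and per-cell speeds relax slowly toward the adapted state on the
scenario's tau ~ 3 h clock (see :mod:`phototrace.scenario`).  The chamber
wall reflects specularly (track analysis discounts wall turns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .geometry import ChamberGeometry
from .protocol import Schedule, _segment_light
from .scenario import AdaptationScenario, MotionType, SCENARIOS

MODE_NAMES = {int(m): m.name.lower() for m in MotionType}

_ROTATION = int(MotionType.ROTATION)
_RUN_TUMBLE = int(MotionType.RUN_TUMBLE)
_CIRCULAR = int(MotionType.CIRCULAR)
_STRAIGHT = int(MotionType.STRAIGHT)
_FROZEN = int(MotionType.FROZEN)
_STOPPED = int(MotionType.STOPPED)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulation run.

    Times are seconds, lengths micrometres, angles radians.
    """

    schedule: Schedule
    n_cells: int = 100
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    scenario: AdaptationScenario = field(default_factory=lambda: SCENARIOS["standard"])
    dt: float = 0.1
    seed: int = 0
    #: latency between light step-up and mode entry, uniform draw bounds (s)
    latency: tuple[float, float] = (0.05, 0.30)
    freeze_duration: float = 2.0
    tumble_rate_in_light: float = 0.125
    #: half-width of the avoidance-reversal jitter (rad)
    reversal_jitter: float = np.pi / 3
    #: positional diffusion coefficient of on-site rotation (um^2/s)
    rot_diffusion: float = 8.5
    #: reflecting confinement radius of on-site rotation (um)
    rot_confine: float = 40.0
    #: gyration radius of the spinning body's centroid wobble (um)
    rot_wobble: float = 12.0
    #: body spin rate during on-site rotation (rad/s)
    spin_rate: float = np.pi
    #: rotational diffusion of the heading while swimming (rad^2/s)
    heading_diffusion: float = 0.01
    #: radius band of circular swimming (um); diameter 300-1200 um
    circle_radius_band: tuple[float, float] = (150.0, 600.0)
    #: global activity multiplier in [0, 1]; below stop_threshold cells stop
    activity_scale: float = 1.0
    stop_threshold: float = 0.2
    #: adaptation-clock offset: elapsed experiment time at schedule t = 0 (s)
    start_elapsed_s: float = 0.0
    #: cadence of emitted track records (s)
    output_dt: float = 1.0 / 3.08

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt > 0.5:
            raise ValueError("dt must be <= 0.5 s for kinematic validity")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.latency[0] <= self.latency[1]):
            raise ValueError("latency bounds must satisfy 0 <= lo <= hi")
        if not 0.0 <= self.activity_scale <= 1.0:
            raise ValueError("activity_scale must be in [0, 1]")


@dataclass
class Population:
    """Vectorised state of all cells (one row per cell)."""

    pos: np.ndarray          # (n, 2) um
    heading: np.ndarray      # (n,) rad
    mode: np.ndarray         # (n,) int8 MotionType
    ptype: np.ndarray        # (n,) int8 current photophobic type
    propensity: np.ndarray   # (n,) fixed adaptation rank in [0, 1)
    speed_rank: np.ndarray   # (n,) fixed speed rank in [0, 1)
    v0: np.ndarray           # (n,) initial speed draw, um/s
    latency_left: np.ndarray  # (n,) s; NaN = inactive
    freeze_left: np.ndarray  # (n,) s
    anchor: np.ndarray       # (n, 2) rotation walk position
    anchor0: np.ndarray      # (n, 2) rotation capture point
    circ_radius: np.ndarray  # (n,) um
    circ_sign: np.ndarray    # (n,) +-1
    spin_sign: np.ndarray    # (n,) +-1

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @classmethod
    def initial(cls, config: SimulationConfig, rng: np.random.Generator) -> "Population":
        """Uniformly distributed motile cells with randomized headings."""
        n = config.n_cells
        geo = config.geometry
        # uniform in the disk by rejection-free polar sampling
        u = rng.uniform(0.0, 1.0, n)
        r = geo.radius * np.sqrt(u) * 0.995
        phi = rng.uniform(0.0, 2 * np.pi, n)
        pos = np.stack([geo.center[0] + r * np.cos(phi), geo.center[1] + r * np.sin(phi)], axis=1)
        lo, hi = config.scenario.initial_speed_range
        speed_rank = rng.uniform(0.0, 1.0, n)
        v0 = lo + speed_rank * (hi - lo)
        propensity = rng.uniform(0.0, 1.0, n)
        pop = cls(
            pos=pos,
            heading=rng.uniform(0.0, 2 * np.pi, n),
            mode=np.full(n, int(MotionType.STRAIGHT), dtype=np.int8),
            ptype=config.scenario.types_for(propensity, config.start_elapsed_s),
            propensity=propensity,
            speed_rank=speed_rank,
            v0=v0,
            latency_left=np.full(n, np.nan),
            freeze_left=np.zeros(n),
            anchor=pos.copy(),
            anchor0=pos.copy(),
            circ_radius=np.full(n, config.circle_radius_band[0]),
            circ_sign=np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0),
            spin_sign=np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0),
        )
        if config.activity_scale < config.stop_threshold:
            pop.mode[:] = int(MotionType.STOPPED)
        return pop

    def speeds(self, config: SimulationConfig, elapsed_s: float) -> np.ndarray:
        """Current swimming speed of each cell, um/s.

        Cells that have adopted a tolerant type migrate their speed into
        that type's adapted band on the scenario's adaptation clock; cells
        still expressing the rotation type keep their initial draw, so the
        dark-swimming activity of the unadapted subpopulation -- the
        baseline of the trace-momentum decrease readout -- is stationary.
        """
        f = np.exp(-elapsed_s / (config.scenario.tau_h * 3600.0))
        v_ad = config.scenario.adapted_speed(self.ptype, self.speed_rank)
        still_rot = self.ptype == int(MotionType.ROTATION)
        v_ad = np.where(still_rot, self.v0, v_ad)
        return (self.v0 * f + v_ad * (1.0 - f)) * config.activity_scale


def _enter_modes(pop: Population, cells: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator, reversal: bool) -> None:
    """Side effects of cells entering their photophobic mode."""
    if not np.any(cells):
        return
    rot = cells & (pop.ptype == int(MotionType.ROTATION))
    rt = cells & (pop.ptype == int(MotionType.RUN_TUMBLE))
    circ = cells & (pop.ptype == int(MotionType.CIRCULAR))
    pop.mode[cells] = pop.ptype[cells]
    if np.any(rot):
        pop.anchor[rot] = pop.pos[rot]
        pop.anchor0[rot] = pop.pos[rot]
    if np.any(rt):
        k = int(rt.sum())
        if reversal:
            # step-up avoidance reversal
            pop.heading[rt] = (pop.heading[rt] + np.pi
                               + rng.uniform(-config.reversal_jitter, config.reversal_jitter, k))
        else:
            pop.heading[rt] = rng.uniform(0.0, 2 * np.pi, k)
    if np.any(circ):
        k = int(circ.sum())
        lo, hi = config.circle_radius_band
        pop.circ_radius[circ] = rng.uniform(lo, hi, k)
        pop.circ_sign[circ] = np.where(rng.uniform(size=k) < 0.5, -1.0, 1.0)


def step_population(pop: Population, t: float, config: SimulationConfig,
                    rng: np.random.Generator,
                    light_on: np.ndarray | None = None) -> Population:
    """Advance the population by one time step ``dt`` starting at time ``t``.

    ``light_on`` may be supplied to bypass the schedule lookup (used by
    tests); otherwise it is evaluated from the schedule at the current
    positions.  Mutates and returns ``pop``.
    """
    dt = config.dt
    if dt <= 0:
        raise ValueError("dt must be > 0")
    elapsed = config.start_elapsed_s + t
    geo = config.geometry

    # slow adaptation: update types; cells never revert to less tolerant types
    pop.ptype = config.scenario.types_for(pop.propensity, elapsed)

    if light_on is None:
        # internal fast path: cells are inside the chamber by construction
        start, proto = config.schedule.segment_at(t)
        light_on = _segment_light(proto, t - start, pop.pos, geo)
    else:
        light_on = np.asarray(light_on, dtype=bool)

    mode = pop.mode
    frozen = mode == _FROZEN
    stopped = mode == _STOPPED
    active = ~frozen & ~stopped

    # thaw frozen cells
    if frozen.any():
        pop.freeze_left[frozen] -= dt
        thaw = frozen & (pop.freeze_left <= 0)
        mode[thaw] = _STRAIGHT

    in_phobic = active & (mode < 3)  # rotation/run_tumble/circular are 0..2
    straightm = active & (mode == _STRAIGHT)
    nontol = pop.ptype != _STRAIGHT
    dark = ~light_on

    # --- step-down: freeze cells whose light went out while responding
    stepdown = in_phobic & dark
    if stepdown.any():
        mode[stepdown] = _FROZEN
        pop.freeze_left[stepdown] = config.freeze_duration
    # cancel pending latencies in the dark
    if dark.any():
        pop.latency_left[dark] = np.nan

    # --- step-up latency countdown for straight swimmers under light
    pending = straightm & light_on & nontol
    if pending.any():
        fresh = pending & np.isnan(pop.latency_left)
        if fresh.any():
            pop.latency_left[fresh] = rng.uniform(
                config.latency[0], config.latency[1], int(fresh.sum()))
        pop.latency_left[pending] -= dt
        trigger = pending & (pop.latency_left <= 0)
        if trigger.any():
            pop.latency_left[trigger] = np.nan
            _enter_modes(pop, trigger, config, rng, reversal=True)

    # --- adaptation switched the type of a currently-responding cell
    mism = in_phobic & light_on & (mode != pop.ptype)
    if mism.any():
        mode[mism & ~nontol] = _STRAIGHT
        _enter_modes(pop, mism & nontol, config, rng, reversal=False)

    # --- kinematics ------------------------------------------------------
    mode = pop.mode
    v = pop.speeds(config, elapsed)

    swim = active & (mode >= 1) & (mode <= 3)  # run_tumble/circular/straight

    # tumbles (Poisson) for run/tumble cells in light: a course change of
    # at least 60 degrees, either sense -- a "direction change" as a trace
    # observer would count it
    rt_moving = mode == _RUN_TUMBLE
    if rt_moving.any():
        tumble = rt_moving & (rng.uniform(size=pop.n) < config.tumble_rate_in_light * dt)
        if tumble.any():
            k = int(tumble.sum())
            ang = rng.uniform(np.pi / 3, np.pi, k)
            sign = np.where(rng.uniform(size=k) < 0.5, -1.0, 1.0)
            pop.heading[tumble] += sign * ang

    # heading update: rotational diffusion + circular turning
    dtheta = rng.normal(0.0, np.sqrt(2.0 * config.heading_diffusion * dt), pop.n)
    circm = mode == _CIRCULAR
    if circm.any():
        dtheta[circm] += (pop.circ_sign[circm] * v[circm] / pop.circ_radius[circm]) * dt
    heading = pop.heading
    heading[swim] += dtheta[swim]

    # translation (vectorised; non-swimmers masked out)
    step_len = np.where(swim, v * dt, 0.0)
    pop.pos[:, 0] += step_len * np.cos(heading)
    pop.pos[:, 1] += step_len * np.sin(heading)

    # on-site rotation: the spinning body's centroid gyrates on a small
    # circle (radius rot_wobble) around an anchor that performs a jittery
    # walk confined near the capture point
    rotm = mode == _ROTATION
    if rotm.any():
        k = int(rotm.sum())
        sigma = np.sqrt(2.0 * config.rot_diffusion * dt)
        anchor = pop.anchor[rotm] + rng.normal(0.0, sigma, (k, 2))
        # reflect inside the confinement disk around the capture point
        confine = max(config.rot_confine - config.rot_wobble, 1.0)
        d = anchor - pop.anchor0[rotm]
        rr = np.hypot(d[:, 0], d[:, 1])
        over = rr > confine
        if over.any():
            fold = (2.0 * confine - rr[over]) / rr[over]
            d[over] *= fold[:, None]
            anchor = pop.anchor0[rotm] + d
        # keep the whole gyration circle inside the chamber: clamp the
        # anchor (and capture point) radially instead of letting the wall
        # clamp drag the cell along the rim
        cxg, cyg = geo.center
        lim = geo.radius - config.rot_wobble - 1.0
        for arr in (anchor, pop.anchor0[rotm]):
            ax = arr[:, 0] - cxg
            ay = arr[:, 1] - cyg
            ra = np.hypot(ax, ay)
            far = ra > lim
            if far.any():
                f2 = lim / ra[far]
                arr[far, 0] = cxg + ax[far] * f2
                arr[far, 1] = cyg + ay[far] * f2
        pop.anchor[rotm] = anchor
        heading[rotm] += pop.spin_sign[rotm] * config.spin_rate * dt
        ph = heading[rotm]
        pop.pos[rotm, 0] = anchor[:, 0] + config.rot_wobble * np.cos(ph)
        pop.pos[rotm, 1] = anchor[:, 1] + config.rot_wobble * np.sin(ph)

    # chamber wall: specular reflection (uniform billiard statistics)
    cx, cy = geo.center
    dx = pop.pos[:, 0] - cx
    dy = pop.pos[:, 1] - cy
    rr2 = dx * dx + dy * dy
    out = rr2 >= geo.radius**2
    if out.any():
        r_out = np.sqrt(rr2[out])
        r_new = np.clip(2.0 * geo.radius - r_out, 0.0, geo.radius * 0.999999)
        scale = r_new / r_out
        pop.pos[out, 0] = cx + dx[out] * scale
        pop.pos[out, 1] = cy + dy[out] * scale
        phi = np.arctan2(dy[out], dx[out])
        heading[out] = np.pi + 2.0 * phi - heading[out]
    return pop


def step_cell(pop: Population, t: float, config: SimulationConfig,
              rng: np.random.Generator, light_on: bool) -> Population:
    """Single-cell convenience wrapper over :func:`step_population`."""
    return step_population(pop, t, config, rng,
                           light_on=np.full(pop.n, light_on, dtype=bool))


def iter_simulation(config: SimulationConfig,
                    duration: float | None = None,
                    pop: Population | None = None,
                    rng: np.random.Generator | None = None,
                    t0: float = 0.0) -> Iterator[tuple[int, float, Population]]:
    """Yield ``(step_index, t, population)`` at every time step.

    The population state is yielded *before* the step at time ``t`` is taken,
    beginning with the initial state at ``t0``.  The same ``Population``
    object is yielded each time (consumers must copy what they keep).
    """
    rng = rng or np.random.default_rng(config.seed)
    pop = pop or Population.initial(config, rng)
    duration = config.schedule.total_duration - t0 if duration is None else duration
    n_steps = int(round(duration / config.dt))
    for k in range(n_steps + 1):
        t = t0 + k * config.dt
        yield k, t, pop
        if k < n_steps:
            step_population(pop, t, config, rng)


def run_simulation(config: SimulationConfig,
                   duration: float | None = None) -> pd.DataFrame:
    """Run the schedule and return a ground-truth track table.

    Records are emitted every ``output_dt`` (snapped to whole steps) with
    columns ``cell_id, t_s, x_um, y_um, mode, speed_um_s``.  Reproducible:
    identical configs (including seed) give bit-identical tables.
    """
    every = max(1, int(round(config.output_dt / config.dt)))
    ids = np.arange(config.n_cells)
    rows: list[pd.DataFrame] = []
    for k, t, pop in iter_simulation(config, duration=duration):
        if k % every:
            continue
        v = pop.speeds(config, config.start_elapsed_s + t)
        rows.append(pd.DataFrame({
            "cell_id": ids,
            "t_s": np.full(config.n_cells, t),
            "x_um": pop.pos[:, 0].copy(),
            "y_um": pop.pos[:, 1].copy(),
            "mode": pop.mode.copy(),
            "speed_um_s": v,
        }))
    out = pd.concat(rows, ignore_index=True)
    out["mode"] = out["mode"].map(MODE_NAMES)
    return out
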