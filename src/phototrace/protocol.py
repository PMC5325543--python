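"""Spatiotemporal blue-light stimulation protocols.

Two stimulation experiments alternate on the same cell population:

* **Experiment A** — spatially uniform pulse train: 15 repeats of 32 s on /
  32 s off, centred in a 26-min segment (5-min dark pads on either side).
* **Experiment B** — a static checkerboard of 580-um squares held on for
  17 min, followed by 9 min of dark, again a 26-min segment.

One AB cycle lasts 55.5 min (the 3.5 min left over after A + B is a dark pad
closing the cycle).  ``full8`` repeats the cycle eight times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ChamberGeometry, checkerboard_parity, BOARD_SQUARE_UM

SEGMENT_DURATION_S = 26.0 * 60.0
CYCLE_DURATION_S = 55.5 * 60.0
BOARD_DURATION_S = 17.0 * 60.0

_KINDS = ("uniform_pulses", "checkerboard", "dark")


@dataclass(frozen=True)
class LightProtocol:
    """One stimulation segment.

    ``kind`` selects the spatial/temporal pattern; durations are seconds,
    lengths micrometres.  For ``uniform_pulses`` the pulse train is centred
    within ``segment_duration``; for ``checkerboard`` the board is on for
    ``board_duration`` starting at segment time zero, dark afterwards.
    """

    kind: str = "dark"
    pulse_on: float = 32.0
    pulse_off: float = 32.0
    n_pulses: int = 15
    board_square: float = BOARD_SQUARE_UM
    board_duration: float = BOARD_DURATION_S
    segment_duration: float = SEGMENT_DURATION_S
    cycle_duration: float = CYCLE_DURATION_S

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        for name in ("pulse_on", "pulse_off", "board_square", "board_duration",
                     "segment_duration", "cycle_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if (self.kind == "uniform_pulses"
                and self.n_pulses * (self.pulse_on + self.pulse_off) > self.segment_duration):
            raise ValueError("pulse train does not fit in segment_duration")
        if self.kind == "checkerboard" and self.board_duration > self.segment_duration:
            raise ValueError("board_duration exceeds segment_duration")

    @property
    def pulse_lead_in(self) -> float:
        """Dark pad before the first pulse (uniform_pulses segments)."""
        return (self.segment_duration - self.n_pulses * (self.pulse_on + self.pulse_off)) / 2.0

    def pulse_window(self, pulse_index: int) -> tuple[float, float]:
        """(start, end) segment time of the on-phase of 1-based ``pulse_index``."""
        if not 1 <= pulse_index <= self.n_pulses:
            raise ValueError(f"pulse_index must be in 1..{self.n_pulses}")
        start = self.pulse_lead_in + (pulse_index - 1) * (self.pulse_on + self.pulse_off)
        return start, start + self.pulse_on


@dataclass(frozen=True)
class Schedule:
    """Ordered list of (protocol, repeat) segments with absolute timing."""

    segments: tuple[tuple[LightProtocol, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty protocol schedule")
        flat, t = [], 0.0
        for proto, rep in self.segments:
            for _ in range(rep):
                flat.append((t, proto))
                t += proto.segment_duration
        object.__setattr__(self, "_flat", tuple(flat))
        object.__setattr__(self, "_starts", np.array([s for s, _ in flat]))

    @property
    def total_duration(self) -> float:
        return sum(p.segment_duration * r for p, r in self.segments)

    def flat(self) -> list[tuple[float, LightProtocol]]:
        """[(segment start time, protocol), ...] with repeats unrolled."""
        return list(self._flat)

    def segment_at(self, t: float) -> tuple[float, LightProtocol]:
        """Segment containing absolute time ``t`` -> (segment start, protocol)."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        i = int(np.searchsorted(self._starts, t, side="right")) - 1
        start, proto = self._flat[i]
        if t > start + proto.segment_duration + 1e-9 and i == len(self._flat) - 1:
            raise ValueError(f"t={t} beyond schedule end {self.total_duration}")
        return start, proto


def _segment_light(proto: LightProtocol, tau: float, xy: np.ndarray,
                   geometry: ChamberGeometry) -> np.ndarray:
    """Vectorised on/off at segment time ``tau`` for positions ``xy``."""
    n = np.asarray(xy).shape[0] if np.asarray(xy).ndim == 2 else 1
    if proto.kind == "dark":
        return np.zeros(n, dtype=bool)
    if proto.kind == "uniform_pulses":
        t_rel = tau - proto.pulse_lead_in
        period = proto.pulse_on + proto.pulse_off
        idx = np.floor(t_rel / period)
        on = (t_rel >= 0) & (idx < proto.n_pulses) & (t_rel % period < proto.pulse_on)
        return np.full(n, bool(on))
    # checkerboard: board on for board_duration from segment start
    if tau >= proto.board_duration:
        return np.zeros(n, dtype=bool)
    par = checkerboard_parity(xy, square=proto.board_square, origin=geometry.center)
    return np.atleast_1d(par)


def light_at(schedule: Schedule | LightProtocol, t: float, xy: np.ndarray,
             geometry: ChamberGeometry | None = None) -> np.ndarray:
    """Blue-light state at time ``t`` (s) and position(s) ``xy`` (um).

    Pure and deterministic.  ``xy`` may be a single (2,) point or an (n, 2)
    array; positions outside the chamber are rejected.
    """
    geometry = geometry or ChamberGeometry()
    if isinstance(schedule, LightProtocol):
        schedule = Schedule(((schedule, 1),))
    xy = np.asarray(xy, dtype=float)
    single = xy.ndim == 1
    pts = xy[None, :] if single else xy
    if not bool(np.all(geometry.contains(pts))):
        raise ValueError("position outside chamber")
    start, proto = schedule.segment_at(t)
    on = _segment_light(proto, t - start, pts, geometry)
    return bool(on[0]) if single else on


# ---------------------------------------------------------------- presets


def expA(**kw) -> LightProtocol:
    """Uniform 32-s on / 32-s off pulse train, 15 repeats, 26-min segment."""
    return LightProtocol(kind="uniform_pulses", **kw)


def expB(**kw) -> LightProtocol:
    """Static 580-um checkerboard, 17 min on then 9 min dark."""
    return LightProtocol(kind="checkerboard", **kw)


def dark(duration: float = SEGMENT_DURATION_S) -> LightProtocol:
    return LightProtocol(kind="dark", segment_duration=duration)


def _cycle_pad(cycle: float = CYCLE_DURATION_S) -> LightProtocol:
    pad = cycle - 2 * SEGMENT_DURATION_S
    return dark(pad)


def cycleAB(n_cycles: int = 1) -> Schedule:
    """``n_cycles`` repeats of [A, B, dark pad] (55.5 min per cycle)."""
    segs: list[tuple[LightProtocol, int]] = []
    for _ in range(n_cycles):
        segs += [(expA(), 1), (expB(), 1), (_cycle_pad(), 1)]
    return Schedule(tuple(segs))


def full8() -> Schedule:
    """The full alternating protocol: eight AB cycles."""
    return cycleAB(8)


PRESETS = {
    "expA": lambda: Schedule(((expA(), 1),)),
    "expB": lambda: Schedule(((expB(), 1),)),
    "cycleAB": lambda: cycleAB(1),
    "full8": full8,
    "dark": lambda: Schedule(((dark(), 1),)),
}
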