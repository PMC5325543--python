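"""Population scenarios: motion-type mixtures and their slow adaptation.

Each cell carries a fixed *propensity* rank in [0, 1).  The population's
photophobic type mixture relaxes exponentially,

    p(t) = p_inf + (p0 - p_inf) * exp(-t / tau),

with tau ~ 3.0 h, and a cell's type at elapsed time t is the bucket its
propensity falls into under the cumulative mixture ordered
rotation -> run/tumble -> circular -> straight.  Because the rotation share
only shrinks (and the tolerant shares only grow) under the standard scenario,
each cell steps through types monotonically and never reverts to a less
tolerant one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class MotionType(IntEnum):
    """Photophobic motion type / instantaneous motion mode."""

    ROTATION = 0
    RUN_TUMBLE = 1
    CIRCULAR = 2
    STRAIGHT = 3
    FROZEN = 4
    STOPPED = 5


#: the four photophobic types, in cumulative-mixture order
PHOTOPHOBIC_TYPES = (
    MotionType.ROTATION,
    MotionType.RUN_TUMBLE,
    MotionType.CIRCULAR,
    MotionType.STRAIGHT,
)

#: adapted swimming-speed bands (um/s) by type: rotation-type cells slow
#: down, run/tumble keep moderate speeds, circular/straight become fast
ADAPTED_SPEED_BANDS = {
    MotionType.ROTATION: (40.0, 70.0),
    MotionType.RUN_TUMBLE: (50.0, 100.0),
    MotionType.CIRCULAR: (120.0, 180.0),
    MotionType.STRAIGHT: (120.0, 180.0),
}


def _norm(p) -> tuple[float, float, float, float]:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,) or np.any(p < 0):
        raise ValueError("proportions must be a non-negative 4-vector")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {s}")
    return tuple(p / s)


@dataclass(frozen=True)
class AdaptationScenario:
    """Initial and asymptotic type mixtures plus the adaptation clock.

    Proportions are ordered (rotation, run/tumble, circular, straight) and
    each vector sums to 1.  ``tau_h`` is the e-folding time in hours.
    """

    name: str = "standard"
    p0: tuple[float, float, float, float] = (0.90, 0.10, 0.00, 0.00)
    p_inf: tuple[float, float, float, float] = (0.10, 0.55, 0.08, 0.27)
    tau_h: float = 3.0
    initial_speed_range: tuple[float, float] = (50.0, 140.0)
    speed_by_type: dict = field(default_factory=lambda: dict(ADAPTED_SPEED_BANDS))

    def __post_init__(self) -> None:
        _norm(self.p0)
        _norm(self.p_inf)
        if self.tau_h <= 0:
            raise ValueError("tau must be > 0")

    def mixture_at(self, elapsed_s: float) -> np.ndarray:
        """Expected type proportions after ``elapsed_s`` seconds."""
        return mixture_at(self.p0, self.p_inf, self.tau_h, elapsed_s)

    def types_for(self, propensity: np.ndarray, elapsed_s: float) -> np.ndarray:
        """Type of each cell given its fixed propensity rank.

        The mapping is the inverse CDF of the time-varying mixture, so the
        expected type fractions equal ``mixture_at`` exactly and each cell
        switches types in a consistent order as the mixture shifts.
        """
        p = self.mixture_at(elapsed_s)
        edges = np.cumsum(p)[:-1]
        idx = np.searchsorted(edges, np.asarray(propensity), side="right")
        return idx.astype(np.int8)  # MotionType values 0..3 in mixture order

    def _speed_bands(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.speed_by_type[t][0] for t in PHOTOPHOBIC_TYPES])
        hi = np.array([self.speed_by_type[t][1] for t in PHOTOPHOBIC_TYPES])
        return lo, hi

    def adapted_speed(self, types: np.ndarray, speed_rank: np.ndarray) -> np.ndarray:
        """Asymptotic speed of each cell: its rank mapped into its type band."""
        if not hasattr(self, "_bands"):
            object.__setattr__(self, "_bands", self._speed_bands())
        lo, hi = self._bands
        types = np.asarray(types, dtype=np.int64)
        return lo[types] + np.asarray(speed_rank) * (hi[types] - lo[types])


def mixture_at(p0, p_inf, tau_h: float, elapsed_s: float) -> np.ndarray:
    """p(t) = p_inf + (p0 - p_inf) * exp(-t/tau)."""
    p0 = np.asarray(p0, dtype=float)
    p_inf = np.asarray(p_inf, dtype=float)
    f = np.exp(-float(elapsed_s) / (tau_h * 3600.0))
    return p_inf + (p0 - p_inf) * f


#: named scenario presets; ``evening``/``red_only``/``kh_cultured`` encode the
#: comparative conditions (circadian-shifted start, 6-h red-light
#: pre-illumination, nutrient-rich KH-medium culture)
SCENARIOS: dict[str, AdaptationScenario] = {
    "standard": AdaptationScenario(),
    "evening": AdaptationScenario(
        name="evening", p0=(0.67, 0.30, 0.01, 0.02), p_inf=(0.10, 0.55, 0.08, 0.27)
    ),
    "red_only": AdaptationScenario(
        name="red_only", p0=(0.11, 0.83, 0.02, 0.04), p_inf=(0.11, 0.83, 0.02, 0.04)
    ),
    "kh_cultured": AdaptationScenario(
        name="kh_cultured",
        p0=(0.10 / 0.99, 0.60 / 0.99, 0.08 / 0.99, 0.21 / 0.99),
        p_inf=(0.10 / 0.99, 0.60 / 0.99, 0.08 / 0.99, 0.21 / 0.99),
    ),
}
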