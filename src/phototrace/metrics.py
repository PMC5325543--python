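"""Trace momentum (TM) and its derived ratios.

TM is the spatial sum of swimming-trace pixels within a region: a proxy for
total locomotor activity that falls when cells switch from line-shaped
straight-swimming traces to spotty on-site-rotation traces.  Derived ratios:

* **decrease ratio**  D = (TM_off - TM_on) / TM_off around a blue-light
  pulse (fraction of activity suppressed by light),
* **separation ratio** S = TM_II / (TM_I + TM_II) over the non-illuminated
  (II) vs illuminated (I) checkerboard areas (escape efficiency),
* **preservation ratio** P = mean TM after / before an illumination episode
  (overall activity retention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

from .geometry import ChamberGeometry, checkerboard_parity, BOARD_SQUARE_UM
from .protocol import LightProtocol
from .traces import TraceImage


def _img(trace) -> np.ndarray:
    return trace.image if isinstance(trace, TraceImage) else np.asarray(trace)


def trace_momentum(trace, mask: np.ndarray | None = None) -> int:
    """Count of trace foreground pixels inside ``mask`` (whole image if None)."""
    img = _img(trace).astype(bool)
    if mask is None:
        return int(img.sum())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != trace shape {img.shape}")
    return int(np.count_nonzero(img & mask))


def tm_series_from_tracks(tm_rows: list[tuple[float, float, float, int, int, int]]
                          ) -> pd.DataFrame:
    """Assemble raw (window_start, window_end, ...) TM rows into a series table."""
    return pd.DataFrame(tm_rows, columns=[
        "window_start", "t_s", "tm_whole", "tm_I", "tm_II", "refresh_index"])


# ------------------------------------------------------------------ ratios


def _windows_inside(df: pd.DataFrame, start: float, end: float) -> pd.DataFrame:
    eps = 1e-6
    return df[(df["window_start"] >= start - eps) & (df["t_s"] <= end + eps)]


@dataclass(frozen=True)
class DecreaseRatioResult:
    value: float
    tm_on: float
    tm_off: float
    n_on: int
    n_off: int
    defined: bool


def decrease_ratio(tm: pd.DataFrame, proto: LightProtocol,
                   pulse_index: int = 4, segment_start: float = 0.0,
                   guard: float = 4.0, column: str = "tm_whole"
                   ) -> DecreaseRatioResult:
    """TM decrease ratio D = (TM_off - TM_on) / TM_off at one pulse.

    ``TM_on`` averages trace windows fully inside the on-phase of
    ``pulse_index``; ``TM_off`` averages windows fully inside the adjacent
    off-phases before and after it, excluding a ``guard`` interval after
    each light-off so the step-down freezing spikes do not bias the plateau.
    """
    on0, on1 = proto.pulse_window(pulse_index)
    on0 += segment_start
    on1 += segment_start
    prev_off = (on0 - proto.pulse_off, on0) if pulse_index > 1 else None
    next_off = (on1, on1 + proto.pulse_off)
    on = _windows_inside(tm, on0, on1)[column]
    off_parts = []
    if prev_off is not None:
        off_parts.append(_windows_inside(tm, prev_off[0] + guard, prev_off[1])[column])
    off_parts.append(_windows_inside(tm, next_off[0] + guard, next_off[1])[column])
    off = pd.concat(off_parts)
    tm_on = float(on.mean()) if len(on) else np.nan
    tm_off = float(off.mean()) if len(off) else np.nan
    defined = len(on) > 0 and len(off) > 0 and tm_off > 0
    d = (tm_off - tm_on) / tm_off if defined else np.nan
    return DecreaseRatioResult(value=d, tm_on=tm_on, tm_off=tm_off,
                               n_on=len(on), n_off=len(off), defined=defined)


@dataclass(frozen=True)
class SeparationRatioResult:
    s_on: float
    s_off: float
    defined_on: bool
    defined_off: bool


def separation_ratio(tm: pd.DataFrame, proto: LightProtocol,
                     segment_start: float = 0.0) -> SeparationRatioResult:
    """TM separation ratio S = mean(TM_II) / (mean(TM_I) + mean(TM_II)).

    Computed separately over the checkerboard on-duration (board period) and
    the off-duration (dark remainder of the segment), from ratio of means.
    """
    def _s(start: float, end: float) -> tuple[float, bool]:
        win = _windows_inside(tm, start, end)
        if len(win) == 0:
            return np.nan, False
        m1, m2 = float(win["tm_I"].mean()), float(win["tm_II"].mean())
        if m1 + m2 <= 0:
            return np.nan, False
        return m2 / (m1 + m2), True

    b0 = segment_start
    b1 = segment_start + proto.board_duration
    seg_end = segment_start + proto.segment_duration
    s_on, ok_on = _s(b0, b1)
    s_off, ok_off = _s(b1, seg_end)
    return SeparationRatioResult(s_on=s_on, s_off=s_off,
                                 defined_on=ok_on, defined_off=ok_off)


def preservation_ratio(tm_before: np.ndarray, tm_after: np.ndarray) -> float:
    """P = mean TM after / mean TM before.  NaN (flagged by warning) when the
    before-mean is zero."""
    tm_before = np.asarray(tm_before, dtype=float)
    tm_after = np.asarray(tm_after, dtype=float)
    if tm_before.size == 0 or tm_after.size == 0:
        raise ValueError("both TM windows must be non-empty")
    mb = tm_before.mean()
    if mb <= 0:
        warnings.warn("preservation ratio undefined: zero TM before")
        return float("nan")
    return float(tm_after.mean() / mb)


# -------------------------------------------------------- per-cell statistics


def per_cell_tm(trace, positions: np.ndarray, types: np.ndarray,
                mask: np.ndarray | None = None, pixel_to_um=None,
                max_unassigned_frac: float = 0.2) -> pd.DataFrame:
    """Mean trace pixels per cell, grouped by motion type.

    Trace connected components are assigned to the nearest cell (by the
    cell's mean window position); each cell's TM is the total pixel count of
    its components.  ``pixel_to_um`` maps (rows, cols) pixel indices to
    physical um (e.g. ``RasterGrid.to_um``); identity if omitted.

    Returns a DataFrame with columns ``type, n_cells, mean_tm_px``.
    """
    img = _img(trace).astype(bool)
    if mask is not None:
        img = img & np.asarray(mask, dtype=bool)
    positions = np.atleast_2d(positions)
    types = np.atleast_1d(types)
    lab = label(img, connectivity=2)
    props = regionprops(lab)
    tm_per_cell = np.zeros(positions.shape[0])
    unassigned = 0
    for p in props:
        r, c = p.centroid
        cen = (pixel_to_um(np.array([r]), np.array([c]))[0] if pixel_to_um is not None
               else np.array([c, r]))
        d = np.hypot(positions[:, 0] - cen[0], positions[:, 1] - cen[1])
        i = int(np.argmin(d))
        # generous gate: a trace component belongs to a cell within one
        # window's travel (~1 mm at top speed)
        if d[i] > 1200.0:
            unassigned += 1
            continue
        tm_per_cell[i] += p.area
    if props and unassigned / len(props) > max_unassigned_frac:
        warnings.warn(f"{unassigned}/{len(props)} trace components unassigned")
    df = pd.DataFrame({"type": types, "tm_px": tm_per_cell})
    out = df.groupby("type", as_index=False).agg(n_cells=("tm_px", "size"),
                                                 mean_tm_px=("tm_px", "mean"))
    return out


def area_occupancy(positions: np.ndarray, geometry: ChamberGeometry | None = None,
                   square: float = BOARD_SQUARE_UM) -> float:
    """Fraction of cells inside the chamber that sit in illuminated area I."""
    geometry = geometry or ChamberGeometry()
    positions = np.atleast_2d(positions)
    inside = geometry.contains(positions)
    if not np.any(inside):
        return float("nan")
    par = checkerboard_parity(positions[inside], square=square, origin=geometry.center)
    return float(np.mean(par))
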