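"""Centroid detection and greedy nearest-neighbour track linking.

At the cell densities of the micro-chamber assay (20-200 cells in ~4.9 mm^2)
greedy frame-to-frame assignment within a speed-gated radius is adequate;
identity switches at rare crossings are tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label, regionprops

DEFAULT_V_MAX = 250.0  # um/s linking gate


@dataclass
class Track:
    """Time-ordered centroid sequence of one cell."""

    cell_id: int
    t: np.ndarray      # (k,) s, strictly increasing
    xy: np.ndarray     # (k, 2) um
    source: str = "detected"  # or "ground_truth"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, t0: float, t1: float) -> "Track":
        sel = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        return Track(self.cell_id, self.t[sel], self.xy[sel], self.source)


def detect_centroids(binary_or_gray: np.ndarray, min_area: float | None = None,
                     foreground_dark: bool = True, intensity_threshold: float | None = None,
                     pixel_to_um=None, expected_cell_area_px: float = 32.0
                     ) -> np.ndarray:
    """Centroids (um or px) of connected components above a minimum area.

    Grayscale input is thresholded (dark cells on a bright field by default,
    at the midpoint intensity unless given).  ``min_area`` defaults to half
    the expected cell body area in pixels.  Returns an (m, 2) array of (x, y)
    positions; empty when nothing is found.
    """
    img = np.asarray(binary_or_gray)
    if img.dtype != bool:
        thr = intensity_threshold if intensity_threshold is not None else \
            (float(img.min()) + float(img.max())) / 2.0
        img = (img < thr) if foreground_dark else (img > thr)
    if min_area is None:
        min_area = expected_cell_area_px / 2.0
    lab = label(img, connectivity=2)
    cents = []
    for p in regionprops(lab):
        if p.area < min_area:
            continue
        r, c = p.centroid
        if pixel_to_um is not None:
            cents.append(pixel_to_um(np.array([r]), np.array([c]))[0])
        else:
            cents.append(np.array([c, r]))
    return np.array(cents).reshape(-1, 2)


def link_tracks(centroid_lists: list[np.ndarray], times: np.ndarray,
                v_max: float = DEFAULT_V_MAX, max_gap: int = 2,
                source: str = "detected") -> list[Track]:
    """Greedy nearest-neighbour linking of per-frame centroids into tracks.

    Each detection links to the closest active track end within
    ``v_max * dt`` (closest pairs first); unmatched detections start new
    tracks; tracks unseen for more than ``max_gap`` frames are closed.
    """
    times = np.asarray(times, dtype=float)
    if len(centroid_lists) != len(times):
        raise ValueError("centroid_lists and times length mismatch")
    next_id = 0
    active: list[dict] = []   # {id, t[], xy[], last_frame}
    closed: list[dict] = []
    for fi, (t, cents) in enumerate(zip(times, centroid_lists)):
        cents = np.asarray(cents).reshape(-1, 2)
        # close stale tracks
        still = []
        for tr in active:
            if fi - tr["last_frame"] > max_gap:
                closed.append(tr)
            else:
                still.append(tr)
        active = still
        if len(cents) == 0:
            continue
        assigned_det = np.zeros(len(cents), dtype=bool)
        if active:
            ends = np.array([tr["xy"][-1] for tr in active])
            end_t = np.array([tr["t"][-1] for tr in active])
            d = np.hypot(cents[:, None, 0] - ends[None, :, 0],
                         cents[:, None, 1] - ends[None, :, 1])
            gate = v_max * (t - end_t)[None, :]
            d = np.where(d <= gate, d, np.inf)
            used_tr = np.zeros(len(active), dtype=bool)
            order = np.argsort(d, axis=None)
            for flat in order:
                i, j = np.unravel_index(flat, d.shape)
                if not np.isfinite(d[i, j]):
                    break
                if assigned_det[i] or used_tr[j]:
                    continue
                tr = active[j]
                tr["t"].append(t)
                tr["xy"].append(cents[i])
                tr["last_frame"] = fi
                assigned_det[i] = True
                used_tr[j] = True
        for i in np.nonzero(~assigned_det)[0]:
            active.append({"id": next_id, "t": [t], "xy": [cents[i]], "last_frame": fi})
            next_id += 1
    closed += active
    closed.sort(key=lambda tr: tr["id"])
    return [Track(tr["id"], np.array(tr["t"]), np.array(tr["xy"]), source=source)
            for tr in closed]


def tracks_from_table(tracks: pd.DataFrame, source: str = "ground_truth"
                      ) -> list[Track]:
    """Convert a simulator track table to Track objects (one per cell_id)."""
    out = []
    for cid, g in tracks.sort_values("t_s").groupby("cell_id"):
        out.append(Track(int(cid), g["t_s"].to_numpy(),
                         g[["x_um", "y_um"]].to_numpy(), source=source))
    return out
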