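"""Direct track-to-trace rasterization (the pipeline's fast path).

Rendering full video for hours of simulated time is wasteful when only the
trace statistics are needed.  The fast path rasterizes each moving cell's
body footprint at every frame time of a superimposition window and ORs the
stamps, approximating the union of difference-image foregrounds that the
full render -> difference -> threshold -> superimpose chain produces.
Frozen and stopped cells leave no trace (a static body cancels in the frame
difference), matching the full path.

Coordinate convention: image row 0 is the top; physical x maps to columns and
y to rows; pixel centres sit at integer indices; micron-to-pixel conversion
rounds to the nearest pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ChamberGeometry
from .scenario import MotionType

DEFAULT_PIXEL_SIZE_UM = 3.0
DEFAULT_CELL_LENGTH_UM = 35.0
DEFAULT_CELL_WIDTH_UM = 10.0


@dataclass(frozen=True)
class RasterGrid:
    """Pixel grid over the chamber.

    ``origin`` is the physical (x, y) um of pixel (row 0, col 0)'s centre.
    """

    shape: tuple[int, int]
    pixel_size: float
    origin: tuple[float, float]

    @classmethod
    def for_chamber(cls, geometry: ChamberGeometry | None = None,
                    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                    margin_px: int = 16) -> "RasterGrid":
        geometry = geometry or ChamberGeometry()
        half = int(np.ceil(geometry.radius / pixel_size)) + margin_px
        n = 2 * half + 1
        ox = geometry.center[0] - half * pixel_size
        oy = geometry.center[1] - half * pixel_size
        return cls(shape=(n, n), pixel_size=pixel_size, origin=(ox, oy))

    def to_px(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) nearest-pixel indices of physical points (um)."""
        xy = np.asarray(xy, dtype=float)
        cols = np.rint((xy[..., 0] - self.origin[0]) / self.pixel_size).astype(np.int64)
        rows = np.rint((xy[..., 1] - self.origin[1]) / self.pixel_size).astype(np.int64)
        return rows, cols

    def to_um(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        x = self.origin[0] + np.asarray(cols) * self.pixel_size
        y = self.origin[1] + np.asarray(rows) * self.pixel_size
        return np.stack([x, y], axis=-1)


def ellipse_offsets(length_um: float, width_um: float, pixel_size: float,
                    theta: float) -> np.ndarray:
    """Flat list of (dr, dc) pixel offsets inside a rotated ellipse.

    The ellipse has semi-axes length/2 (along ``theta``) and width/2, centred
    on a pixel centre.
    """
    a = length_um / 2.0 / pixel_size
    b = width_um / 2.0 / pixel_size
    r = int(np.ceil(a))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    # x -> col, y -> row
    u = dc * ct + dr * st
    v = -dc * st + dr * ct
    inside = (u / a) ** 2 + (v / max(b, 0.5)) ** 2 <= 1.0
    return np.stack([dr[inside], dc[inside]], axis=1)


def disk_offsets(radius_um: float, pixel_size: float) -> np.ndarray:
    r_px = radius_um / pixel_size
    r = int(np.ceil(r_px))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    inside = dr**2 + dc**2 <= r_px**2
    return np.stack([dr[inside], dc[inside]], axis=1)


#: effective stamp radius of a gyrating cell, as a fraction of the body
#: half-length: frame differencing sees only the tip region of the pivoting
#: body (calibrated once against the render -> difference -> superimpose
#: chain on single-cell stacks)
ROTATION_STAMP_FRAC = 0.60


class TraceRasterizer:
    """OR-accumulates cell footprints over superimposition windows.

    Swimming cells stamp an oriented body ellipse per frame (headings are
    quantized into ``n_heading_bins``); on-site rotating cells stamp the
    tip-region disk their gyrating body's difference image covers (the body
    core cancels in differencing); frozen/stopped cells stamp nothing.
    """

    def __init__(self, grid: RasterGrid,
                 cell_length: float = DEFAULT_CELL_LENGTH_UM,
                 cell_width: float = DEFAULT_CELL_WIDTH_UM,
                 n_heading_bins: int = 16):
        self.grid = grid
        self.cell_length = cell_length
        self.cell_width = cell_width
        self.n_bins = n_heading_bins
        w = grid.shape[1]
        self._flat_stamps = []
        for b in range(n_heading_bins):
            theta = (b + 0.5) * np.pi / n_heading_bins  # ellipse has pi symmetry
            off = ellipse_offsets(cell_length, cell_width, grid.pixel_size, theta)
            self._flat_stamps.append(off[:, 0] * w + off[:, 1])
        disk = disk_offsets(ROTATION_STAMP_FRAC * cell_length / 2.0,
                            grid.pixel_size)
        self._disk_flat = disk[:, 0] * w + disk[:, 1]
        self._npix = grid.shape[0] * grid.shape[1]

    def heading_bin(self, heading: np.ndarray) -> np.ndarray:
        return (np.floor(np.mod(heading, np.pi) / np.pi * self.n_bins)
                .astype(np.int64) % self.n_bins)

    def stamp_frame(self, img_flat: np.ndarray, pos: np.ndarray,
                    heading: np.ndarray, mode: np.ndarray) -> None:
        """OR one frame's moving-cell footprints into ``img_flat`` (bool)."""
        rows, cols = self.grid.to_px(pos)
        base = rows * self.grid.shape[1] + cols
        moving = (mode != int(MotionType.FROZEN)) & (mode != int(MotionType.STOPPED))
        rot = moving & (mode == int(MotionType.ROTATION))
        swim = moving & ~rot
        if np.any(rot):
            idx = (base[rot][:, None] + self._disk_flat[None, :]).ravel()
            img_flat[idx] = True
        if np.any(swim):
            bins = self.heading_bin(heading[swim])
            bswim = base[swim]
            for b in np.unique(bins):
                sel = bins == b
                idx = (bswim[sel][:, None] + self._flat_stamps[b][None, :]).ravel()
                img_flat[idx] = True

    def window_image(self, frames: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
                     ) -> np.ndarray:
        """Boolean trace image from a window's (pos, heading, mode) frames."""
        img = np.zeros(self._npix, dtype=bool)
        for pos, heading, mode in frames:
            self.stamp_frame(img, pos, heading, mode)
        return img.reshape(self.grid.shape)


def rasterize_traces(frames: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                     grid: RasterGrid | None = None,
                     cell_length: float = DEFAULT_CELL_LENGTH_UM,
                     cell_width: float = DEFAULT_CELL_WIDTH_UM) -> np.ndarray:
    """One-shot trace image from per-frame (pos, heading, mode) states."""
    grid = grid or RasterGrid.for_chamber()
    return TraceRasterizer(grid, cell_length, cell_width).window_image(frames)
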