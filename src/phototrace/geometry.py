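"""Chamber geometry and checkerboard region masks.

The cells are confined to a circular micro-chamber (default diameter 2.49 mm).
Chamber depth (140 um in the physical device) confines swimming to a plane, so
the model is strictly 2-D.  The patterned stimulus is a checkerboard of 580-um
squares whose corner lattice is anchored at the chamber centre: a 90-degree
rotation about the centre then exchanges illuminated and non-illuminated
squares, so areas I and II tile the chamber interior with exactly equal area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default chamber diameter, um
CHAMBER_DIAMETER_UM = 2490.0
#: default checkerboard square edge, um
BOARD_SQUARE_UM = 580.0


@dataclass(frozen=True)
class ChamberGeometry:
    """Circular 2-D swimming arena.

    Parameters
    ----------
    diameter:
        Chamber diameter in micrometres (> 0).
    center:
        Chamber centre in the simulation frame, um.  Simulation coordinates
        are chamber-centred by default.
    depth:
        Physical chamber depth, um.  Recorded for provenance; unused by the
        2-D model.
    """

    diameter: float = CHAMBER_DIAMETER_UM
    center: tuple[float, float] = (0.0, 0.0)
    depth: float = 140.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"chamber diameter must be > 0, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points strictly inside the chamber.

        ``xy`` has shape (..., 2), in um.
        """
        xy = np.asarray(xy, dtype=float)
        d2 = (xy[..., 0] - self.center[0]) ** 2 + (xy[..., 1] - self.center[1]) ** 2
        return d2 < self.radius**2


def checkerboard_parity(
    xy: np.ndarray,
    square: float = BOARD_SQUARE_UM,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Checkerboard colour of each point: ``True`` for area I (illuminated).

    The board's corner lattice passes through ``origin`` (default: the chamber
    centre).  Squares with even ``floor(x/s) + floor(y/s)`` parity are area I.
    """
    xy = np.asarray(xy, dtype=float)
    ix = np.floor((xy[..., 0] - origin[0]) / square).astype(np.int64)
    iy = np.floor((xy[..., 1] - origin[1]) / square).astype(np.int64)
    return (ix + iy) % 2 == 0


def area_masks(
    shape: tuple[int, int],
    pixel_size: float,
    geometry: ChamberGeometry | None = None,
    square: float = BOARD_SQUARE_UM,
    frame_origin: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Build boolean region masks on a pixel grid.

    Returns a dict with keys ``whole`` (chamber interior), ``area_I`` and
    ``area_II``.  ``area_I & area_II`` is empty and their union equals
    ``whole`` exactly.

    Parameters
    ----------
    shape:
        (rows, cols) of the pixel grid.
    pixel_size:
        um per pixel.
    frame_origin:
        Physical (x, y) um of the pixel (row 0, col 0) centre.  Defaults to
        centring the chamber in the frame.
    """
    geometry = geometry or ChamberGeometry()
    rows, cols = shape
    if frame_origin is None:
        fx = geometry.center[0] - (cols - 1) / 2.0 * pixel_size
        fy = geometry.center[1] - (rows - 1) / 2.0 * pixel_size
    else:
        fx, fy = frame_origin
    x = fx + np.arange(cols) * pixel_size
    y = fy + np.arange(rows) * pixel_size
    xx, yy = np.meshgrid(x, y)
    pts = np.stack([xx, yy], axis=-1)
    whole = geometry.contains(pts)
    par = checkerboard_parity(pts, square=square, origin=geometry.center)
    return {
        "whole": whole,
        "area_I": whole & par,
        "area_II": whole & ~par,
    }


def reflect_into_chamber(
    xy: np.ndarray, geometry: ChamberGeometry, heading: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Specularly reflect positions that left the chamber back inside.

    Positions are folded across the circular wall; headings (if given) have
    their radial component flipped for the reflected cells.  A single
    reflection handles all displacements small relative to the radius.
    """
    xy = np.array(xy, dtype=float, copy=True)
    cx, cy = geometry.center
    dx = xy[..., 0] - cx
    dy = xy[..., 1] - cy
    r = np.hypot(dx, dy)
    out = r >= geometry.radius
    if np.any(out):
        # fold the radial overshoot back: r -> 2R - r (cap at just inside)
        r_out = r[out]
        r_new = np.clip(2.0 * geometry.radius - r_out, 0.0, geometry.radius * 0.999999)
        scale = np.where(r_out > 0, r_new / np.where(r_out > 0, r_out, 1.0), 0.0)
        xy[..., 0][out] = cx + dx[out] * scale
        xy[..., 1][out] = cy + dy[out] * scale
        if heading is not None:
            heading = np.array(heading, dtype=float, copy=True)
            # reflect heading across the tangent at the wall contact point
            phi = np.arctan2(dy[out], dx[out])
            heading[out] = np.pi + 2.0 * phi - heading[out]
    return xy, heading
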