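"""Synthetic bright-field frame rendering of simulated cell states.

Cells are drawn as filled dark ellipses (length along the heading) on a
bright background with additive Gaussian noise, 8-bit grayscale.  The
absolute pixel calibration (um/px, body size, intensities) is a package
default, not a measured microscope property; trace statistics quoted in
pixel units hold under this documented default calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .rasterize import (RasterGrid, ellipse_offsets, DEFAULT_PIXEL_SIZE_UM,
                        DEFAULT_CELL_LENGTH_UM, DEFAULT_CELL_WIDTH_UM)

DEFAULT_FRAME_RATE = 3.08  # fps; 4x the 0.77-Hz trace refresh


@dataclass(frozen=True)
class RenderConfig:
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_shape: tuple[int, int] = (864, 864)
    frame_rate: float = DEFAULT_FRAME_RATE
    cell_length: float = DEFAULT_CELL_LENGTH_UM
    cell_width: float = DEFAULT_CELL_WIDTH_UM
    foreground_intensity: int = 60
    background_intensity: int = 200
    noise_sd: float = 3.0
    #: physical (x, y) um of pixel (0, 0); None centres the origin
    frame_origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.foreground_intensity == self.background_intensity:
            raise ValueError("foreground and background intensities must differ")

    def grid(self) -> RasterGrid:
        rows, cols = self.frame_shape
        if self.frame_origin is not None:
            origin = self.frame_origin
        else:
            origin = (-(cols - 1) / 2.0 * self.pixel_size,
                      -(rows - 1) / 2.0 * self.pixel_size)
        return RasterGrid(shape=self.frame_shape, pixel_size=self.pixel_size,
                          origin=origin)


@dataclass
class FrameStack:
    """Ordered grayscale frames with strictly increasing timestamps."""

    frames: np.ndarray        # (F, rows, cols) uint8
    timestamps: np.ndarray    # (F,) s
    config: RenderConfig = field(default_factory=RenderConfig)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (F, rows, cols)")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("frames/timestamps length mismatch")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def save(self, path: str | Path) -> None:
        """Multi-page TIFF plus a JSON sidecar with timestamps and config."""
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        side = {"timestamps": self.timestamps.tolist(),
                "render_config": asdict(self.config)}
        path.with_suffix(".json").write_text(json.dumps(side))

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        path = Path(path)
        frames = tifffile.imread(path)
        side = json.loads(path.with_suffix(".json").read_text())
        rc = dict(side["render_config"])
        rc["frame_shape"] = tuple(rc["frame_shape"])
        if rc.get("frame_origin") is not None:
            rc["frame_origin"] = tuple(rc["frame_origin"])
        return cls(frames=frames, timestamps=np.array(side["timestamps"]),
                   config=RenderConfig(**rc))


def render_frame(pos: np.ndarray, heading: np.ndarray, config: RenderConfig,
                 rng: np.random.Generator | None = None,
                 cell_ids: np.ndarray | None = None) -> np.ndarray:
    """Render one grayscale frame from cell positions (um) and headings.

    Raises if any cell falls outside the frame, naming the offending cell.
    Pure given the rng state.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    heading = np.atleast_1d(np.asarray(heading, dtype=float))
    grid = config.grid()
    rows, cols = grid.to_px(pos)
    r_stamp = int(np.ceil(config.cell_length / 2.0 / config.pixel_size))
    h, w = config.frame_shape
    bad = ((rows < r_stamp) | (rows >= h - r_stamp)
           | (cols < r_stamp) | (cols >= w - r_stamp))
    if np.any(bad):
        i = int(np.nonzero(bad)[0][0])
        cid = int(cell_ids[i]) if cell_ids is not None else i
        raise ValueError(f"cell {cid} outside frame at ({pos[i, 0]:.1f}, {pos[i, 1]:.1f}) um")
    img = np.full(config.frame_shape, float(config.background_intensity))
    for i in range(pos.shape[0]):
        off = ellipse_offsets(config.cell_length, config.cell_width,
                              config.pixel_size, heading[i])
        img[rows[i] + off[:, 0], cols[i] + off[:, 1]] = config.foreground_intensity
    if rng is not None and config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_stack(tracks, config: RenderConfig,
                 rng: np.random.Generator | None = None) -> FrameStack:
    """Render a frame stack from a track table by nearest-time state lookup.

    ``tracks`` is a DataFrame with columns ``cell_id, t_s, x_um, y_um`` and
    optionally ``heading`` (otherwise headings are inferred from consecutive
    displacements).  Frames are placed at ``k / frame_rate`` from the first
    track time to the last.
    """
    import pandas as pd  # local: keep module import light

    if len(tracks) == 0:
        raise ValueError("empty track table")
    tracks = tracks.sort_values(["t_s", "cell_id"])
    times = np.sort(tracks["t_s"].unique())
    t0, t1 = times[0], times[-1]
    n_frames = int(np.floor((t1 - t0) * config.frame_rate)) + 1
    frame_times = t0 + np.arange(n_frames) / config.frame_rate
    by_time = {t: g for t, g in tracks.groupby("t_s")}
    has_heading = "heading" in tracks.columns

    # infer headings from displacement when not provided
    headings_by_time: dict[float, np.ndarray] = {}
    prev: pd.DataFrame | None = None
    prev_head: np.ndarray | None = None
    for t in times:
        g = by_time[t]
        if has_heading:
            headings_by_time[t] = g["heading"].to_numpy()
        else:
            xy = g[["x_um", "y_um"]].to_numpy()
            if prev is None:
                headings_by_time[t] = np.zeros(len(g))
            else:
                d = xy - prev[["x_um", "y_um"]].to_numpy()
                h = np.arctan2(d[:, 1], d[:, 0])
                still = np.hypot(d[:, 0], d[:, 1]) < 1e-9
                h[still] = prev_head[still]
                headings_by_time[t] = h
            prev, prev_head = g, headings_by_time[t]
            continue
        prev, prev_head = g, headings_by_time[t]

    frames = np.empty((n_frames, *config.frame_shape), dtype=np.uint8)
    for k, tf in enumerate(frame_times):
        i = int(np.argmin(np.abs(times - tf)))
        g = by_time[times[i]]
        frames[k] = render_frame(g[["x_um", "y_um"]].to_numpy(),
                                 headings_by_time[times[i]], config, rng=rng,
                                 cell_ids=g["cell_id"].to_numpy())
    return FrameStack(frames=frames, timestamps=frame_times, config=config)
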