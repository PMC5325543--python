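"""Swimming-trace extraction: differencing, thresholding, superimposing.

A grayscale frame stack is converted to binary motion images by absolute
frame differencing and thresholding; binary frames are then OR-superimposed
over a sliding window (default 3.9 s) refreshed at 0.77 Hz, mirroring a live
trace display.  Windows are trailing (causal): each trace image ends at its
refresh tick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

DEFAULT_WINDOW_S = 3.9
DEFAULT_REFRESH_HZ = 0.77


@dataclass(frozen=True)
class BinaryFrame:
    """Thresholded difference image; timestamped at the later source frame."""

    image: np.ndarray
    timestamp: float


@dataclass(frozen=True)
class TraceImage:
    """OR-superimposed binary trace over [window_start, window_end]."""

    image: np.ndarray
    window_start: float
    window_end: float
    refresh_index: int


def difference_threshold(frame_t: np.ndarray, frame_prev: np.ndarray,
                         threshold: float, timestamp: float = 0.0) -> BinaryFrame:
    """Pixelwise ``|frame_t - frame_prev| > threshold`` as a binary frame."""
    frame_t = np.asarray(frame_t)
    frame_prev = np.asarray(frame_prev)
    if frame_t.shape != frame_prev.shape:
        raise ValueError(f"frame shapes differ: {frame_t.shape} vs {frame_prev.shape}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    diff = np.abs(frame_t.astype(np.int16) - frame_prev.astype(np.int16))
    return BinaryFrame(image=diff > threshold, timestamp=timestamp)


def superimpose(binary_frames: list[BinaryFrame | np.ndarray],
                window_start: float | None = None,
                window_end: float | None = None,
                refresh_index: int = 0) -> TraceImage:
    """Pixelwise logical OR of binary frames within one window.

    Monotone: adding frames never removes foreground.
    """
    if not binary_frames:
        raise ValueError("empty superimposition window")
    imgs, times = [], []
    for bf in binary_frames:
        if isinstance(bf, BinaryFrame):
            imgs.append(bf.image)
            times.append(bf.timestamp)
        else:
            imgs.append(np.asarray(bf, dtype=bool))
    out = imgs[0].astype(bool).copy()
    for im in imgs[1:]:
        if im.shape != out.shape:
            raise ValueError("binary frame shapes differ within window")
        out |= im
    if window_start is None:
        window_start = min(times) if times else 0.0
    if window_end is None:
        window_end = max(times) if times else 0.0
    return TraceImage(image=out, window_start=window_start,
                      window_end=window_end, refresh_index=refresh_index)


def default_threshold(stack: np.ndarray, noise_sd: float | None = None) -> float:
    """4 x the difference-image noise SD when the frame noise level is
    known (differencing doubles the variance: sd_diff = sd * sqrt(2)),
    else Otsu on the pooled absolute-difference histogram."""
    if noise_sd is not None and noise_sd > 0:
        return 4.0 * noise_sd * np.sqrt(2.0)
    stack = np.asarray(stack)
    diffs = np.abs(np.diff(stack.astype(np.int16), axis=0))
    if diffs.max() == 0:
        return 1.0
    return float(threshold_otsu(diffs.ravel()))


def trace_series(stack: np.ndarray, timestamps: np.ndarray,
                 window: float = DEFAULT_WINDOW_S,
                 refresh: float = DEFAULT_REFRESH_HZ,
                 threshold: float | None = None,
                 noise_sd: float | None = None) -> list[TraceImage]:
    """Ordered trace images, one per refresh tick after the first full window.

    Refresh ticks are ``t0 + window + k / refresh``.  A binary frame (stamped
    at its later source frame) belongs to the window whose interval
    ``(end - window, end]`` contains its timestamp.  The number of outputs
    depends only on stack duration, window and refresh -- not content.
    """
    stack = np.asarray(stack)
    timestamps = np.asarray(timestamps, dtype=float)
    if stack.shape[0] != timestamps.shape[0]:
        raise ValueError("stack and timestamps lengths differ")
    if stack.shape[0] < 2:
        raise ValueError("need at least two frames")
    t0, t_end = timestamps[0], timestamps[-1]
    if t_end - t0 < window:
        raise ValueError(f"stack duration {t_end - t0:.2f}s shorter than window {window}s")
    if threshold is None:
        threshold = default_threshold(stack, noise_sd=noise_sd)
    binary = [difference_threshold(stack[i], stack[i - 1], threshold, timestamps[i])
              for i in range(1, stack.shape[0])]
    btimes = np.array([b.timestamp for b in binary])
    out: list[TraceImage] = []
    k = 0
    eps = 1e-9
    while True:
        end = t0 + window + k / refresh
        if end > t_end + eps:
            break
        start = end - window
        sel = np.nonzero((btimes > start + eps) & (btimes <= end + eps))[0]
        frames = [binary[i] for i in sel]
        if frames:
            out.append(superimpose(frames, window_start=start, window_end=end,
                                   refresh_index=k))
        else:  # structurally empty window (content-independent count)
            out.append(TraceImage(image=np.zeros(stack.shape[1:], dtype=bool),
                                  window_start=start, window_end=end, refresh_index=k))
        k += 1
    return out
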