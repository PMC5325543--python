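"""Photophobic motion-type classification of tracks over a pulse window.

Four types are distinguished during a 32-s blue-light pulse: on-site rotation
(spatially confined), run/tumble (two or more abrupt reorientations),
circular swimming (a good large-circle fit with sustained turning), and
straightforward swimming (everything else).  Near-stationary cells are
excluded as irregular, mirroring the <10% of cells dropped from the motion
analysis in this assay type.

Decision order (first match wins):

1. ``irregular_excluded`` if mean speed < 5 um/s;
2. ``rotation``   if gyration radius < 40 um;
3. ``run_tumble`` if >= 2 tumble events;
4. ``circular``   if the circle fit is tight (rms residual < 0.35 x radius),
   the fitted diameter lies in the observed large-circle band (150-1500 um)
   and the net turning exceeds 3*pi/2;
5. ``straight``   otherwise.

The circular gate uses *net* (signed) turning: heading diffusion makes the
absolute turning of any long track large, but only sustained same-sense
curvature accumulates net turning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ChamberGeometry
from .tracking import Track

R_ROT_UM = 40.0
#: turns whose vertex lies this close to the chamber wall are discounted
WALL_MARGIN_UM = 70.0
TURN_THRESHOLD_RAD = np.deg2rad(30.0)
TURN_WINDOW_S = 2.0
MIN_SPEED_UM_S = 5.0
CIRCLE_MIN_DIAMETER_UM = 150.0
CIRCLE_MAX_DIAMETER_UM = 1500.0
CIRCLE_RESIDUAL_FRAC = 0.35
CIRCLE_MIN_TURNING_RAD = 1.5 * np.pi

LABELS = ("rotation", "run_tumble", "circular", "straight", "irregular_excluded")


@dataclass(frozen=True)
class TrackFeatures:
    mean_speed: float        # um/s, path length / duration
    path_length: float       # um
    net_displacement: float  # um
    gyration_radius: float   # um
    tumble_count: int
    total_turning: float     # rad, |net signed heading change| over the window
    circle_radius: float     # um, algebraic (Kasa) fit
    circle_rms: float        # um, rms radial residual


def swimming_speed(track: Track, window: tuple[float, float] | None = None) -> float:
    """Path length / duration over the window, um/s."""
    tr = track.window(*window) if window is not None else track
    if tr.t.size < 2:
        raise ValueError("need >= 2 samples for a speed")
    dur = tr.t[-1] - tr.t[0]
    if dur <= 0:
        raise ValueError("zero-duration window")
    steps = np.hypot(*np.diff(tr.xy, axis=0).T)
    return float(steps.sum() / dur)


def detect_tumbles(track: Track, window: tuple[float, float] | None = None,
                   turn_threshold: float = TURN_THRESHOLD_RAD,
                   turn_window: float = TURN_WINDOW_S,
                   geometry: ChamberGeometry | None = None,
                   wall_margin: float = WALL_MARGIN_UM) -> list[float]:
    """Times of abrupt reorientations (tumbles).

    A tumble is an abrupt heading change exceeding ``turn_threshold``
    between consecutive samples, relative to the track's smooth-turning
    baseline (the median per-step turn), with successive events separated
    by at least ``turn_window``.  Detrending keeps smooth sustained turning
    (circular swimming) from registering as tumbling; the single-step
    criterion targets the effectively instantaneous reorientations this
    organism shows.  Near the chamber wall (within ``wall_margin``), turns
    consistent with the specular reflection law (outgoing heading =
    pi + 2*phi - incoming, phi the polar angle of the contact point) are
    discounted when a ``geometry`` is given: wall bounces are not
    behavioural direction changes, while genuine tumbles at the wall
    rarely satisfy the law.
    """
    tr = track.window(*window) if window is not None else track
    dt_med = float(np.median(np.diff(tr.t))) if tr.t.size >= 2 else 0.0
    if dt_med > turn_window:
        raise ValueError("track sampling coarser than the turn window")
    tt, dh = _turn_series(tr, geometry, wall_margin)
    if dh.size == 0:
        return []
    dh = dh - np.median(dh)  # remove the smooth-turning baseline
    # a turn falling between two samples splits across consecutive
    # increments: test pairwise sums as well
    big = np.abs(dh) > turn_threshold
    if dh.size >= 2:
        big[:-1] |= np.abs(dh[:-1] + dh[1:]) > turn_threshold
    events: list[float] = []
    last_event = -np.inf
    for j in np.nonzero(big)[0]:
        if tt[j + 1] - last_event >= turn_window:
            events.append(float(tt[j + 1]))
            last_event = tt[j + 1]
    return events


def _turn_series(tr: Track, geometry: ChamberGeometry | None,
                 wall_margin: float = WALL_MARGIN_UM
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step heading increments with wall bounces discounted.

    Returns (segment mid-times, wrapped heading increments); increments at
    near-wall vertices that satisfy the specular reflection law are zeroed.
    """
    if tr.t.size < 3:
        return np.empty(0), np.empty(0)
    d = np.diff(tr.xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    moving = steps > 1e-6
    headings = np.arctan2(d[:, 1], d[:, 0])
    t_mid = (tr.t[:-1] + tr.t[1:]) / 2.0
    idx = np.nonzero(moving)[0]
    if idx.size < 2:
        return np.empty(0), np.empty(0)
    h = headings[idx]
    tt = t_mid[idx]
    dh = np.angle(np.exp(1j * np.diff(h)))
    if geometry is not None and dh.size:
        med = float(np.median(dh))  # smooth-turning baseline (arc curvature)
        vtx = tr.xy[idx[1:]]
        vx = vtx[:, 0] - geometry.center[0]
        vy = vtx[:, 1] - geometry.center[1]
        near_wall = np.hypot(vx, vy) > geometry.radius - wall_margin
        phi = np.arctan2(vy, vx)
        # chord-sampled headings of a curving track carry ~|med| bias per
        # segment; widen the law tolerance accordingly
        tol = 0.35 + 2.0 * abs(med)
        pred = np.pi + 2.0 * phi - h[:-1]      # specular reflection law
        resid = np.abs(np.angle(np.exp(1j * (h[1:] - pred))))
        # only abrupt (baseline-relative) turns are candidate bounces:
        # smooth arcs grazing the wall keep their increments
        cand = np.abs(dh - med) > 0.25
        drop = (near_wall & cand & (resid < tol)
                & (np.cos(h[:-1] - phi) > 0.0)   # incoming wallward
                & (np.cos(h[1:] - phi) < 0.0))   # outgoing inward
        if dh.size >= 2:
            # a bounce split between two samples: combined turn obeys the law
            pred2 = np.pi + 2.0 * phi[:-1] - h[:-2]
            resid2 = np.abs(np.angle(np.exp(1j * (h[2:] - pred2))))
            pair = (near_wall[:-1] & (resid2 < tol)
                    & (np.abs(dh[:-1] + dh[1:] - 2 * med) > 0.5)
                    & (np.cos(h[:-2] - phi[:-1]) > 0.0)
                    & (np.cos(h[2:] - phi[:-1]) < 0.0))
            drop[:-1] |= pair
            drop[1:] |= pair
        # replace discounted turns with the baseline turn, not zero, so the
        # discount itself leaves no artificial kink in a curving track
        dh = np.where(drop, med, dh)
    return tt, dh


def _kasa_circle(xy: np.ndarray) -> tuple[float, float]:
    """Algebraic circle fit; returns (radius, rms radial residual)."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return np.inf, np.inf
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        return np.inf, np.inf
    r = float(np.sqrt(r2))
    resid = np.hypot(x - cx, y - cy) - r
    return r, float(np.sqrt(np.mean(resid**2)))


def track_features(track: Track, window: tuple[float, float] | None = None,
                   turn_threshold: float = TURN_THRESHOLD_RAD,
                   turn_window: float = TURN_WINDOW_S,
                   geometry: ChamberGeometry | None = None) -> TrackFeatures:
    """Kinematic features of one track over a pulse window."""
    tr = track.window(*window) if window is not None else track
    if tr.t.size < 3:
        raise ValueError("track too short for features")
    d = np.diff(tr.xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    path = float(steps.sum())
    dur = float(tr.t[-1] - tr.t[0])
    net = float(np.hypot(*(tr.xy[-1] - tr.xy[0])))
    centred = tr.xy - tr.xy.mean(axis=0)
    gyration = float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))
    # net turning from behavioural (non-bounce) heading increments only
    _, dh = _turn_series(tr, geometry)
    turning = float(abs(dh.sum())) if dh.size else 0.0
    tumbles = detect_tumbles(tr, turn_threshold=turn_threshold,
                             turn_window=turn_window, geometry=geometry)
    radius, rms = _kasa_circle(tr.xy)
    return TrackFeatures(mean_speed=path / dur, path_length=path,
                         net_displacement=net, gyration_radius=gyration,
                         tumble_count=len(tumbles), total_turning=turning,
                         circle_radius=radius, circle_rms=rms)


def classify_motion(features: TrackFeatures, r_rot: float = R_ROT_UM,
                    min_speed: float = MIN_SPEED_UM_S) -> str:
    """Assign one of the photophobic motion labels from features.

    Deterministic given features (order-free across tracks).
    """
    if features.mean_speed < min_speed:
        return "irregular_excluded"
    if features.gyration_radius < r_rot:
        return "rotation"
    if features.tumble_count >= 2:
        return "run_tumble"
    diameter = 2.0 * features.circle_radius
    if (np.isfinite(features.circle_radius)
            and features.circle_rms < CIRCLE_RESIDUAL_FRAC * features.circle_radius
            and CIRCLE_MIN_DIAMETER_UM <= diameter <= CIRCLE_MAX_DIAMETER_UM
            and features.total_turning >= CIRCLE_MIN_TURNING_RAD):
        return "circular"
    return "straight"


def classify_population(tracks: list[Track], window: tuple[float, float],
                        min_coverage: float = 0.8,
                        tumble_context: float = 3.0,
                        geometry: ChamberGeometry | None = None) -> pd.DataFrame:
    """Label every track over a pulse window.

    Tracks covering less than ``min_coverage`` of the window get a withheld
    (NaN) label.  Tumble detection looks back ``tumble_context`` seconds
    before the window so the reorientation at light step-up is visible
    against the pre-pulse straight run; all other features use the window
    proper.  Wall-bounce turns are discounted from tumble counting
    (``geometry`` defaults to the standard chamber).  Returns columns
    ``cell_id, label, mean_speed, tumble_count, gyration_radius``.
    """
    geometry = geometry or ChamberGeometry()
    t0, t1 = window
    rows = []
    for tr in tracks:
        sub = tr.window(t0, t1)
        if sub.t.size < 3 or sub.duration < min_coverage * (t1 - t0):
            rows.append((tr.cell_id, None, np.nan, 0, np.nan))
            continue
        f = track_features(sub, geometry=geometry)
        if tumble_context > 0:
            ext = tr.window(t0 - tumble_context, t1)
            try:
                n_t = len(detect_tumbles(ext, geometry=geometry))
            except ValueError:
                n_t = f.tumble_count
            # the look-back can contribute at most the one step-up event
            from dataclasses import replace as _replace
            f = _replace(f, tumble_count=max(f.tumble_count,
                                             min(n_t, f.tumble_count + 1)))
        rows.append((tr.cell_id, classify_motion(f), f.mean_speed,
                     f.tumble_count, f.gyration_radius))
    return pd.DataFrame(rows, columns=["cell_id", "label", "mean_speed",
                                       "tumble_count", "gyration_radius"])


def label_proportions(labels: pd.DataFrame) -> pd.Series:
    """Proportions of the four motion types among non-excluded tracks."""
    ok = labels.dropna(subset=["label"])
    ok = ok[ok["label"] != "irregular_excluded"]
    counts = ok["label"].value_counts()
    props = counts / counts.sum() if counts.sum() else counts.astype(float)
    return props.reindex(["rotation", "run_tumble", "circular", "straight"],
                         fill_value=0.0)
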