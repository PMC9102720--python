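"""Amnioserosa cell dynamics in the standard analysis window.

The measured window opens when the dorsal gap is 50 µm wide and lasts
15 min.  Within it, the six most central AS cells are followed; each
cell's apical-area series is converted to a normalized relative area
trace n(t) = A(t)/Ā − 1, from which pulse count and pulse amplitude
("height") are extracted by prominence-filtered peak detection.  Cell
shape is summarized by the convexity shape index

    N(t_x) = AS_area(t_x) / Ch_area(t_x),

the ratio of the cell polygon's area to that of its convex hull (1 for a
convex cell, < 1 for a wavy one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from shapely.geometry import Polygon

from .closure_kinetics import HoleSeries
from .movie_io import CellTrack

__all__ = [
    "PulseTrace",
    "window_start",
    "select_central_cells",
    "normalize_trace",
    "detect_pulses",
    "shape_index",
    "cell_area_at_gap",
    "sheet_metrics",
    "WINDOW_MIN",
    "GAP_WIDTH_UM",
]

WINDOW_MIN = 15.0  #: analysis window length, min
GAP_WIDTH_UM = 50.0  #: gap width that opens the window, µm
DEFAULT_PROMINENCE = 0.02  #: pulse prominence threshold (20% of WT amplitude)


@dataclass
class PulseTrace:
    """One cell's normalized relative apical-area trace with its pulses."""

    track_id: int
    times: np.ndarray  # s within the window
    n: np.ndarray  # normalized relative apical area
    pulses: list[tuple[float, float, float]]  # (peak_time, trough_time, height)
    amplitude_mean: float
    count: int
    flat: bool = False  # True when no pulse cleared the prominence threshold
    extras: dict = field(default_factory=dict)


def window_start(hole: HoleSeries, gap_width: float = GAP_WIDTH_UM,
                 window_min: float = WINDOW_MIN) -> int:
    """First frame of the hole series with W <= gap_width.

    Errors if the hole never narrows to the gap width, or if the series
    ends less than one window length after the start.
    """
    below = np.flatnonzero(hole.W <= gap_width)
    if below.size == 0:
        raise ValueError(
            f"closure insufficient: width never reaches {gap_width} µm "
            f"(min {hole.W.min():.1f} µm)"
        )
    start = int(below[0])
    if (hole.n_frames - 1 - start) * hole.dt < window_min:
        raise ValueError(
            f"movie ends {(hole.n_frames - 1 - start) * hole.dt:.0f} min after "
            f"window start; need {window_min:.0f} min"
        )
    return start


def select_central_cells(tracks: list[CellTrack], hole, k: int = 6,
                         frame: int = 0) -> list[CellTrack]:
    """The k tracks whose centroids are nearest the hole centroid.

    ``hole`` may be a HoleSeries (centroid taken at its window-start frame)
    or a plain (x, y) center.  Track centroids are evaluated at ``frame``
    of the track movie (0 when the AS movie opens at the 50-µm gap, as the
    synthetic sheets do).  Ties break toward the smaller track id.
    """
    if isinstance(hole, HoleSeries):
        center = hole.centroid(window_start(hole))
    else:
        center = tuple(hole)
    alive = [tr for tr in tracks if frame in tr.frames]
    if len(alive) < k:
        raise ValueError(f"only {len(alive)} tracks alive at frame {frame}, need {k}")

    def key(tr: CellTrack):
        cx, cy = tr.centroid(frame)
        return ((cx - center[0]) ** 2 + (cy - center[1]) ** 2, tr.track_id)

    return sorted(alive, key=key)[:k]


def normalize_trace(area_series) -> np.ndarray:
    """Normalized relative apical area: n(t) = A(t)/Ā − 1, Ā = window mean.

    Zero-mean by construction, hence comparable across cell sizes.  This is
    the single place to swap in an alternative normalization.
    """
    A = np.asarray(area_series, dtype=float)
    if A.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    if np.any(A <= 0):
        raise ValueError("areas must be positive")
    return A / A.mean() - 1.0


def detect_pulses(n, dt: float = 30.0, prominence: float = DEFAULT_PROMINENCE,
                  track_id: int = -1) -> PulseTrace:
    """Detect pulses in a normalized relative area trace.

    A pulse is a local maximum with topographic prominence >= ``prominence``.
    Its height is peak value minus the preceding detected trough; peaks with
    no interior preceding trough (a cycle truncated by the window edge)
    count toward the pulse number but not the amplitude mean, so partial
    first cycles cannot bias the amplitude downward.  If no pulse has an
    interior trough, the window-start value serves as the trough.
    """
    n = np.asarray(n, dtype=float)
    if n.size < 3:
        raise ValueError("need at least 3 samples for pulse detection")
    times = np.arange(n.size) * dt
    peaks, _ = find_peaks(n, prominence=prominence)
    troughs, _ = find_peaks(-n, prominence=prominence)
    pulses: list[tuple[float, float, float]] = []
    heights = []
    for p in peaks:
        prior = troughs[troughs < p]
        if prior.size:
            tr = int(prior[-1])
            h = float(n[p] - n[tr])
            pulses.append((float(times[p]), float(times[tr]), h))
            heights.append(h)
        else:
            pulses.append((float(times[p]), float(times[0]), float(n[p] - n[0])))
    if heights:
        amp = float(np.mean(heights))
    elif len(pulses):
        amp = float(np.mean([h for _, _, h in pulses]))
    else:
        amp = 0.0
    return PulseTrace(
        track_id=track_id,
        times=times,
        n=n,
        pulses=pulses,
        amplitude_mean=amp,
        count=len(peaks),
        flat=len(peaks) == 0,
    )


def shape_index(polygon) -> float:
    """Convexity shape index N = area(polygon) / area(convex hull) ∈ (0, 1]."""
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    if poly.area <= 0:
        raise ValueError("degenerate polygon with zero area")
    return float(poly.area / poly.convex_hull.area)


def cell_area_at_gap(tracks: list[CellTrack], hole: HoleSeries,
                     gap_width: float = GAP_WIDTH_UM, k: int = 6,
                     frame: int = 0) -> dict[int, tuple[float, float]]:
    """Apical area and perimeter (µm², µm) of the k central cells at the
    frame where the gap reaches ``gap_width``.

    ``frame`` indexes the track movie at that moment (0 when the AS movie
    starts at the 50-µm gap, as the synthetic sheets do).
    """
    window_start(hole, gap_width)  # validates the gap is reached
    selected = select_central_cells(tracks, hole, k=k)
    out = {}
    for tr in selected:
        i = tr.frames.index(frame)
        out[tr.track_id] = (float(tr.areas[i]), float(tr.perimeters[i]))
    return out


def sheet_metrics(tracks: list[CellTrack], hole: HoleSeries, dt: float = 30.0,
                  prominence: float = DEFAULT_PROMINENCE, k: int = 6):
    """Per-cell AS metrics for one embryo's sheet movie over the window.

    The track movie is assumed to open at the 50-µm-gap frame and span the
    15-min window (the synthetic sheets are rendered exactly so).  Returns
    a tidy DataFrame with one row per selected central cell: apical area
    and perimeter at the window start, mean shape index over the window,
    pulse amplitude and pulse count.
    """
    import pandas as pd

    selected = select_central_cells(tracks, hole, k=k)
    n_window = int(WINDOW_MIN * 60 / dt) + 1
    rows = []
    for tr in selected:
        frames = [f for f in tr.frames if f < n_window]
        areas = tr.area_series(frames)
        trace = detect_pulses(normalize_trace(areas), dt=dt,
                              prominence=prominence, track_id=tr.track_id)
        n_vals = [shape_index(tr.polygons[tr.frames.index(f)]) for f in frames]
        i0 = tr.frames.index(frames[0])
        rows.append(
            {
                "track_id": tr.track_id,
                "area_um2": float(tr.areas[i0]),
                "perimeter_um": float(tr.perimeters[i0]),
                "shape_index": float(np.mean(n_vals)),
                "amplitude": trace.amplitude_mean,
                "pulse_count": trace.count,
            }
        )
    return pd.DataFrame(rows)
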