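"""Calibrated label-movie I/O, cell-polygon extraction, and frame-to-frame track linking.

A :class:`LabelMovie` is the segmented input of the pipeline: a time stack of
2-D integer label images (label 0 = background) with spatial calibration
(µm/px), a frame interval, and the index of timepoint zero (the frame right
after germ-band retraction).  Cells are converted to sub-pixel boundary
polygons and linked across frames by intersection-over-union into
:class:`CellTrack` objects carrying per-frame area and perimeter series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMovie",
    "CellTrack",
    "read_label_movie",
    "write_label_movie",
    "polygons_from_labels",
    "link_tracks",
    "tracks_to_frame",
    "write_tracks_csv",
]


@dataclass
class LabelMovie:
    """Time stack of 2-D integer label images with calibration.

    Pixel centers sit at integer pixel coordinates; ``origin`` is the µm
    coordinate (x, y) of the center of pixel (row 0, col 0), so that
    ``x = col * px_size + origin[0]`` and ``y = row * px_size + origin[1]``.
    """

    frames: np.ndarray  # (T, H, W) non-negative integers
    px_size: float  # µm / px
    dt: float  # seconds between frames
    t0_frame: int = 0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise ValueError("label images must have an integer pixel type")
        if self.frames.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.px_size > 0:
            raise ValueError("px_size must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.t0_frame < self.n_frames:
            raise ValueError("t0_frame out of range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds relative to timepoint zero."""
        return (np.arange(self.n_frames) - self.t0_frame) * self.dt


@dataclass
class CellTrack:
    """One cell followed through consecutive frames.

    ``polygons[i]`` is the CCW outer-boundary polygon (µm) of the cell in
    frame ``frames[i]``; the frame set is contiguous.
    """

    track_id: int
    frames: list[int]
    polygons: list[np.ndarray]
    areas: np.ndarray = field(default=None)  # type: ignore[assignment]
    perimeters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frames != list(range(self.frames[0], self.frames[-1] + 1)):
            raise ValueError("track frame set must be contiguous")
        if self.areas is None:
            polys = [Polygon(p) for p in self.polygons]
            self.areas = np.array([p.area for p in polys])
            self.perimeters = np.array([p.length for p in polys])
        if np.any(self.areas <= 0):
            raise ValueError("track polygons must have positive area")

    def centroid(self, frame: int) -> tuple[float, float]:
        poly = Polygon(self.polygons[self.frames.index(frame)])
        c = poly.centroid
        return (c.x, c.y)

    def area_series(self, frames: list[int]) -> np.ndarray:
        idx = [self.frames.index(f) for f in frames]
        return self.areas[idx]


def read_label_movie(
    path,
    px_size: float,
    dt: float,
    t0_frame: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LabelMovie:
    """Read a multi-page TIFF label stack and attach calibration.

    Raises on non-integer pixel types, ragged page shapes or non-positive
    calibration values; 2-D single-page files are promoted to one frame.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"ragged page shapes in {path}: {sorted(shapes)}")
    stack = np.stack(pages)
    if not np.issubdtype(stack.dtype, np.integer):
        raise ValueError(f"label movie must have integer pixels, got {stack.dtype}")
    return LabelMovie(stack, px_size=px_size, dt=dt, t0_frame=t0_frame, origin=origin)


def write_label_movie(path, movie: LabelMovie, sidecar: bool = True) -> None:
    """Write a multi-page 16-bit TIFF plus a JSON calibration sidecar."""
    if movie.frames.max() >= 2**16:
        raise ValueError("labels exceed 16-bit range")
    tifffile.imwrite(path, movie.frames.astype(np.uint16), photometric="minisblack")
    if sidecar:
        meta = {
            "px_size_um": movie.px_size,
            "dt_s": movie.dt,
            "t0_frame": movie.t0_frame,
            "origin_um": list(movie.origin),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel outer boundary of a binary mask, as (row, col) vertices."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    # outermost contour = the one enclosing the largest area
    contour = max(contours, key=lambda c: abs(_shoelace(c)))
    return contour - 1.0  # undo padding offset


def _shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygons_from_labels(
    frame: np.ndarray,
    px_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> dict[int, np.ndarray]:
    """Extract one CCW outer-boundary polygon (µm) per label of a label image.

    Boundaries are traced at the half-pixel level (marching squares at 0.5),
    so the polygon area of a label agrees with its pixel count to ~1 px².
    A label split into several connected components keeps only its largest
    component (with a warning), mirroring how a corrupted segmentation would
    be curated.
    """
    frame = np.asarray(frame)
    out: dict[int, np.ndarray] = {}
    labels = np.unique(frame)
    labels = labels[labels > 0]
    slices = ndimage.find_objects(frame)
    for lab in labels:
        sl = slices[int(lab) - 1]
        if sl is None:  # pragma: no cover - unique() guarantees presence
            continue
        mask = frame[sl] == lab
        n_comp, comp = 1, None
        comp, n_comp = ndimage.label(mask)
        if n_comp > 1:
            logger.warning("label %d has %d components; keeping largest", lab, n_comp)
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, n_comp + 1))
            mask = comp == (1 + int(np.argmax(sizes)))
        rc = _trace_boundary(mask)
        rc = rc + np.array([sl[0].start, sl[1].start])
        xy = np.column_stack(
            [rc[:, 1] * px_size + origin[0], rc[:, 0] * px_size + origin[1]]
        )
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        # enforce CCW orientation in (x, y)
        if _shoelace(xy) < 0:
            xy = xy[::-1]
        out[int(lab)] = xy
    return out


def _overlap_table(a: np.ndarray, b: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel-overlap counts between labels of two aligned label images."""
    sel = (a > 0) & (b > 0)
    if not sel.any():
        return {}
    pairs = a[sel].astype(np.int64) * (int(b.max()) + 1) + b[sel].astype(np.int64)
    uniq, counts = np.unique(pairs, return_counts=True)
    k = int(b.max()) + 1
    return {(int(u // k), int(u % k)): int(c) for u, c in zip(uniq, counts)}


def link_tracks(movie: LabelMovie, iou_threshold: float = 0.5) -> list[CellTrack]:
    """Link labels across consecutive frames into cell tracks.

    Greedy bipartite matching on descending intersection-over-union; a match
    is accepted iff IoU >= ``iou_threshold``.  Ties break toward the larger
    IoU, then the smaller incoming label.  Unmatched labels start or
    terminate tracks.  AS cells move far less than a cell diameter between
    frames, so greedy matching is sufficient here.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to link tracks")
    frame_polys = [
        polygons_from_labels(f, movie.px_size, movie.origin) for f in movie.frames
    ]
    # active: label in current frame -> track key
    tracks: dict[int, list[tuple[int, int]]] = {}
    next_id = 0
    active: dict[int, int] = {}
    for lab in frame_polys[0]:
        tracks[next_id] = [(0, lab)]
        active[lab] = next_id
        next_id += 1
    for fi in range(1, movie.n_frames):
        prev, cur = movie.frames[fi - 1], movie.frames[fi]
        areas_prev = dict(zip(*[list(v) for v in np.unique(prev[prev > 0], return_counts=True)]))
        areas_cur = dict(zip(*[list(v) for v in np.unique(cur[cur > 0], return_counts=True)]))
        overlaps = _overlap_table(prev, cur)
        cands = []
        for (la, lb), inter in overlaps.items():
            union = areas_prev[la] + areas_cur[lb] - inter
            iou = inter / union
            if iou >= iou_threshold:
                cands.append((iou, la, lb))
        cands.sort(key=lambda t: (-t[0], t[1]))
        new_active: dict[int, int] = {}
        used_prev: set[int] = set()
        for iou, la, lb in cands:
            if la in used_prev or lb in new_active:
                continue
            if la in active:
                tid = active[la]
                tracks[tid].append((fi, lb))
                new_active[lb] = tid
                used_prev.add(la)
        for lb in frame_polys[fi]:
            if lb not in new_active:
                tracks[next_id] = [(fi, lb)]
                new_active[lb] = next_id
                next_id += 1
        active = new_active
    out = []
    for tid, steps in tracks.items():
        frames = [f for f, _ in steps]
        polys = [frame_polys[f][lab] for f, lab in steps]
        out.append(CellTrack(track_id=tid, frames=frames, polygons=polys))
    return out


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    """Long-format per-frame table of track geometry."""
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": f,
                    "area_um2": tr.areas[i],
                    "perimeter_um": tr.perimeters[i],
                }
            )
    return pd.DataFrame(rows)


def write_tracks_csv(path, tracks: list[CellTrack]) -> None:
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            verts = ";".join(f"{x:.4f} {y:.4f}" for x, y in tr.polygons[i])
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": f,
                    "area_um2": tr.areas[i],
                    "perimeter_um": tr.perimeters[i],
                    "vertices": verts,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
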