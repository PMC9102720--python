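"""Ground-truthed synthetic dorsal-closure embryos.

Generates the three kinds of data the quantification pipeline consumes,
with a fully known ground truth:

* an eye-shaped dorsal hole whose width W(t) and length L(t) shrink
  according to genotype-specific piecewise-linear speed profiles
  (leading-edge convergence and zipping), sampled every 4 min;
* an amnioserosa (AS) sheet of polygonal cells tiling an ellipse, each
  cell's apical area pulsing sinusoidally,
  A_i(t) = A0_i (1 + a sin(2π f t / T + φ_i)), rasterized to a label movie
  every 30 s over the standard 15-min analysis window;
* filopodia polyline annotations for six engrailed stripes.

The genotype presets (wild type and the four formin mutants dia, frl,
DAAM, form3) encode each genotype's closure duration, initial and maximal
convergence speed, and zipping-speed profile; the initial hole size is
derived from the speed-profile integral so that closure completes exactly
at the preset duration.  Everything is deterministic under a seed: the
seed moves only noise and pulsation phases, never W(t) or L(t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram
from skimage.draw import polygon as draw_polygon

from .closure_kinetics import HoleSeries
from .movie_io import LabelMovie

logger = logging.getLogger(__name__)

__all__ = [
    "EmbryoPreset",
    "GroundTruth",
    "TrueCell",
    "PRESET_NAMES",
    "make_preset",
    "simulate_closure",
    "simulate_as_sheet",
    "simulate_filopodia",
    "write_simulation",
]


@dataclass
class EmbryoPreset:
    """Generative parameter bundle for one genotype.

    Speed knots are (time min, speed µm/min) pairs, linearly interpolated,
    held constant beyond the last knot.  ``pulse_amp`` is the relative
    apical-area amplitude a; ``pulse_period`` the pulsation period in s;
    ``freq_mult`` a dimensionless frequency multiplier; ``waviness`` the
    relative radial boundary-perturbation amplitude.
    """

    name: str
    conv_knots: list[tuple[float, float]]
    zip_knots: list[tuple[float, float]]
    duration: float  # min, time of last conv knot
    n_cells: int = 24
    pulse_amp: float = 0.10
    pulse_period: float = 230.0  # s
    freq_mult: float = 1.0
    waviness: float = 0.15
    noise_sd: float = 0.5  # px, vertex jitter when noise is on
    px_size: float = 0.2  # µm/px
    dt_closure: float = 4.0  # min
    dt_as: float = 30.0  # s

    def __post_init__(self) -> None:
        for knots, label in ((self.conv_knots, "conv"), (self.zip_knots, "zip")):
            times = [t for t, _ in knots]
            if times[0] != 0 or any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{label}_knots times must strictly increase from 0")
            if any(v < 0 for _, v in knots):
                raise ValueError(f"{label}_knots speeds must be >= 0")
        if self.duration != self.conv_knots[-1][0]:
            raise ValueError("duration must equal the last conv knot time")
        if not 0 <= self.pulse_amp < 0.5:
            raise ValueError("pulse_amp must be in [0, 0.5)")
        if not self.pulse_period > 0:
            raise ValueError("pulse_period must be > 0")
        if self.n_cells < 6:
            raise ValueError("n_cells must be >= 6")
        if self.W0 <= 0 or self.L0 <= 0:
            raise ValueError("speed profiles must integrate to positive hole size")

    @property
    def W0(self) -> float:
        """Initial hole width: integral of the convergence-speed profile."""
        return float(_profile_integral(self.conv_knots, np.array([self.duration]))[0])

    @property
    def L0(self) -> float:
        """Initial hole length: integral of the zipping-speed profile."""
        return float(_profile_integral(self.zip_knots, np.array([self.duration]))[0])


@dataclass
class TrueCell:
    """Ground-truth geometry of one synthetic AS cell."""

    cell_id: int
    areas: np.ndarray  # exact polygon area per frame, µm²
    polygons: list[np.ndarray]  # per-frame vertices, µm


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyzers must recover."""

    hole: HoleSeries
    tracks: list[TrueCell] = field(default_factory=list)
    #: cell_id -> (normalized peak-to-trough amplitude, pulse count in window)
    pulses_true: dict[int, tuple[float, int]] = field(default_factory=dict)
    #: stripe -> list of filopodium lengths, µm
    filopodia_true: dict[int, list[float]] | None = None


# ---------------------------------------------------------------------------
# presets
#
# Convergence-speed knots encode each genotype's printed initial speed,
# maximal speed (with its timing) and closure duration; wild-type zipping
# knots encode the 0.7 -> 1.7 µm/min first phase, the plateau and the final
# 2.5 µm/min boost.  Mutant zipping profiles encode the printed start
# speeds, delayed/lowered first-phase maxima and first-84-min means.
# Pulsation: wild-type relative amplitude 0.10 with a 230-s period gives
# ~4 pulses per 15-min window; mutants use 0.045 (a 55% reduction, inside
# the measured 50-60% range) and mildly shifted frequencies.

_PRESETS: dict[str, dict] = {
    "WT": dict(
        conv_knots=[(0, 0.55), (40, 1.12), (100, 0.30), (174, 0.30)],
        zip_knots=[(0, 0.7), (84, 1.5), (90, 1.7), (150, 1.7), (174, 2.5)],
        duration=174,
        pulse_amp=0.10,
        freq_mult=1.0,
        waviness=0.15,
    ),
    "frl": dict(
        conv_knots=[(0, 0.45), (60, 0.71), (120, 0.71), (204, 0.0)],
        zip_knots=[(0, 0.4), (84, 0.4), (158, 0.9), (204, 1.2)],
        duration=204,
        pulse_amp=0.045,
        freq_mult=0.9,
        waviness=0.15,
    ),
    "DAAM": dict(
        conv_knots=[(0, 0.50), (40, 0.95), (100, 0.25), (219, 0.05)],
        zip_knots=[(0, 0.2625), (90, 1.2), (150, 0.6), (219, 1.0)],
        duration=219,
        pulse_amp=0.045,
        freq_mult=0.9,
        waviness=0.03,
    ),
    "form3": dict(
        conv_knots=[(0, 0.28), (40, 0.85), (120, 0.20), (245, 0.10)],
        zip_knots=[(0, 0.35), (90, 1.1), (120, 0.8), (215, 0.8), (245, 1.5)],
        duration=245,
        pulse_amp=0.045,
        freq_mult=1.1,
        waviness=0.03,
    ),
    "dia": dict(
        conv_knots=[(0, 0.27), (52, 0.80), (140, 0.20), (274, 0.10)],
        zip_knots=[(0, 0.6), (84, 0.4), (138, 1.0), (274, 1.2)],
        duration=274,
        pulse_amp=0.045,
        freq_mult=1.1,
        waviness=0.03,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str) -> EmbryoPreset:
    """Build the named genotype preset.

    Raises ``ValueError`` listing the valid names for an unknown genotype.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    return EmbryoPreset(name=name, **_PRESETS[name])


# ---------------------------------------------------------------------------
# speed profiles and hole geometry


def _profile_speed(knots, t):
    """Piecewise-linear speed at times t (flat extension beyond last knot)."""
    kt = np.array([k[0] for k in knots], dtype=float)
    kv = np.array([k[1] for k in knots], dtype=float)
    return np.interp(np.asarray(t, dtype=float), kt, kv)


def _profile_integral(knots, t_query):
    """Exact cumulative integral of the piecewise-linear profile at t_query.

    Exact because the trapezoid rule is evaluated on the union of knot and
    query times, between which the profile is linear.
    """
    t_query = np.asarray(t_query, dtype=float)
    kt = np.array([k[0] for k in knots], dtype=float)
    grid = np.union1d(np.union1d(kt, t_query), [0.0])
    v = _profile_speed(knots, grid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(grid))])
    return np.interp(t_query, grid, cum)


def _eye_contour(W: float, L: float, n_arc: int = 121) -> np.ndarray | None:
    """Eye-shaped contour: two parabolic arcs meeting at the canthi
    (±L/2, 0) with mid-width W.  Odd n_arc samples the apex at x = 0, so
    vertex extents are exactly (W, L)."""
    if W <= 0 or L <= 0:
        return None
    x = np.linspace(-L / 2, L / 2, n_arc)
    y = (W / 2) * (1 - (2 * x / L) ** 2)
    top = np.column_stack([x, y])
    bottom = np.column_stack([x[::-1][1:-1], -y[::-1][1:-1]])
    return np.vstack([top, bottom])


def simulate_closure(
    preset: EmbryoPreset, seed: int = 0, noise: bool = False
) -> HoleSeries:
    """Render the shrinking dorsal hole as a per-frame contour series.

    W(t) = W0 - ∫v_conv and L(t) = L0 - ∫v_zip (clipped at 0), sampled at
    the closure frame interval and extended two frames past completion.
    With ``noise`` on, vertices get Gaussian jitter of sd noise_sd·px_size.
    """
    dt = preset.dt_closure
    n_frames = int(np.floor(preset.duration / dt)) + 3
    t = np.arange(n_frames) * dt
    W = preset.W0 - _profile_integral(preset.conv_knots, t)
    L = preset.L0 - _profile_integral(preset.zip_knots, t)
    W[np.abs(W) < 1e-9] = 0.0
    L[np.abs(L) < 1e-9] = 0.0
    W = np.maximum(W, 0.0)
    L = np.maximum(L, 0.0)
    rng = np.random.default_rng(seed)
    contours: list[np.ndarray | None] = []
    for k in range(n_frames):
        c = _eye_contour(W[k], L[k])
        if c is not None and noise:
            c = c + rng.normal(0, preset.noise_sd * preset.px_size, size=c.shape)
        contours.append(c)
    if noise:
        # widths/lengths re-measured as vertex extents of the jittered
        # contours (jitter can let the arcs cross near the canthi, so the
        # extent is taken directly rather than through polygon validation)
        W = np.array([np.ptp(c[:, 1]) if c is not None else 0.0 for c in contours])
        L = np.array([np.ptp(c[:, 0]) if c is not None else 0.0 for c in contours])
    return HoleSeries(contours=contours, W=W, L=L, dt=dt, t0_frame=0)


# ---------------------------------------------------------------------------
# AS sheet

_SHEET_RX, _SHEET_RY = 60.0, 30.0  # tissue ellipse semi-axes, µm
_MARGIN = 5.0  # µm of background around the tissue
_N_ANGLES = 96  # radial boundary samples per cell
_WAVE_LOBES = 6  # lobes of the boundary-waviness perturbation
_REST_SHRINK = 0.80  # rest-state cell size relative to its tessellation cell
_WINDOW_S = 900.0  # standard analysis window, s


def _ellipse_polygon(rx: float, ry: float, n: int = 180) -> Polygon:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([rx * np.cos(th), ry * np.sin(th)]))


def _lloyd_tessellation(rng, n_cells: int, n_iter: int = 8) -> list[Polygon]:
    """Centroidal Voronoi tessellation of the tissue ellipse."""
    ellipse = _ellipse_polygon(_SHEET_RX, _SHEET_RY)
    pts = []
    while len(pts) < n_cells:
        x = rng.uniform(-_SHEET_RX, _SHEET_RX)
        y = rng.uniform(-_SHEET_RY, _SHEET_RY)
        if (x / _SHEET_RX) ** 2 + (y / _SHEET_RY) ** 2 < 1:
            pts.append((x, y))
    pts = np.array(pts)
    for _ in range(n_iter):
        vor = voronoi_diagram(MultiPoint(pts), envelope=ellipse.buffer(50))
        cells = [None] * len(pts)
        for geom in vor.geoms:
            for i, p in enumerate(pts):
                if cells[i] is None and geom.contains(Point(p)):
                    cells[i] = geom.intersection(ellipse)
                    break
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    return cells


def _radial_profile(cell: Polygon, centroid: np.ndarray) -> np.ndarray:
    """Distance from the centroid to the (convex) cell boundary at
    _N_ANGLES equally spaced angles."""
    th = np.linspace(0, 2 * np.pi, _N_ANGLES, endpoint=False)
    u = np.column_stack([np.cos(th), np.sin(th)])
    verts = np.asarray(cell.exterior.coords)[:-1]
    p1 = verts
    p2 = np.roll(verts, -1, axis=0)
    e = p2 - p1  # (m, 2)
    r = np.full(_N_ANGLES, np.inf)
    for j in range(_N_ANGLES):
        d = u[j]
        # solve centroid + t d = p1 + s e  for each edge
        denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
        rhs = p1 - centroid
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / denom
            s = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / denom
        ok = (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 0)
        if ok.any():
            r[j] = t[ok].min()
    return r


def _pulse_count_truth(freq_mult: float, period: float, phase: float) -> int:
    """Number of maxima of sin(2π f t / T + φ) for t in [0, window]."""
    omega = 2 * np.pi * freq_mult / period
    # maxima where omega t + phase = pi/2 + 2 pi k
    k_lo = int(np.ceil((phase - np.pi / 2) / (2 * np.pi)))
    k_hi = int(np.floor((omega * _WINDOW_S + phase - np.pi / 2) / (2 * np.pi)))
    return max(0, k_hi - k_lo + 1)


def simulate_as_sheet(
    preset: EmbryoPreset, seed: int = 0, noise: bool = False
) -> tuple[LabelMovie, GroundTruth]:
    """Render the pulsing AS cell sheet as a label movie over the standard
    window (first 50-µm-gap frame to +15 min, every 30 s).

    Cells are a centroidal Voronoi tessellation of an ellipse; each cell's
    rest polygon is its tessellation cell shrunk about its centroid (the
    gap plays the role of the membrane signal), optionally perturbed by a
    sinusoidal radial waviness, then scaled through time so its area
    follows A0_i (1 + a sin(2π f t / T + φ_i)).  Because every rendered
    polygon stays strictly inside its own convex tessellation cell, labels
    can never overlap; if a waviness setting would break that bound it is
    damped with a warning.
    """
    rng = np.random.default_rng(seed)
    a, T, fm = preset.pulse_amp, preset.pulse_period, preset.freq_mult
    w = preset.waviness
    max_factor = _REST_SHRINK * (1 + w) * np.sqrt(1 + a)
    if max_factor > 0.99:
        w_damped = 0.99 / (_REST_SHRINK * np.sqrt(1 + a)) - 1
        logger.warning(
            "waviness %.3f would let cells overlap; damped to %.3f", w, w_damped
        )
        w = max(w_damped, 0.0)

    cells = _lloyd_tessellation(rng, preset.n_cells)
    centroids = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    th = np.linspace(0, 2 * np.pi, _N_ANGLES, endpoint=False)
    unit = np.column_stack([np.cos(th), np.sin(th)])
    phases = rng.uniform(0, 2 * np.pi, preset.n_cells)
    wave_phases = rng.uniform(0, 2 * np.pi, preset.n_cells)

    base_polys = []
    for i, cell in enumerate(cells):
        r = _radial_profile(cell, centroids[i])
        r_rest = r * _REST_SHRINK * (1 + w * np.sin(_WAVE_LOBES * th + wave_phases[i]))
        base_polys.append(centroids[i] + r_rest[:, None] * unit)

    # timing: window starts when the hole is 50 µm wide (closure frames)
    hole = simulate_closure(preset, seed=seed, noise=False)
    start_idx = int(np.flatnonzero(hole.W <= 50.0)[0])
    t_start = start_idx * preset.dt_closure * 60.0  # s

    n_frames = int(round(_WINDOW_S / preset.dt_as)) + 1
    t_local = np.arange(n_frames) * preset.dt_as  # s since window start
    h_px = int(round(2 * (_SHEET_RY + _MARGIN) / preset.px_size))
    w_px = int(round(2 * (_SHEET_RX + _MARGIN) / preset.px_size))
    origin = (-(_SHEET_RX + _MARGIN), -(_SHEET_RY + _MARGIN))
    frames = np.zeros((n_frames, h_px, w_px), dtype=np.uint16)

    tracks = []
    omega = 2 * np.pi * fm / T
    for i in range(preset.n_cells):
        base = base_polys[i]
        base_area = Polygon(base).area
        scale = np.sqrt(1 + a * np.sin(omega * t_local + phases[i]))
        polys, areas = [], []
        for k in range(n_frames):
            verts = centroids[i] + scale[k] * (base - centroids[i])
            if noise:
                verts = verts + rng.normal(
                    0, preset.noise_sd * preset.px_size, size=verts.shape
                )
            polys.append(verts)
            areas.append(base_area * scale[k] ** 2)
            rr = (verts[:, 1] - origin[1]) / preset.px_size
            cc = (verts[:, 0] - origin[0]) / preset.px_size
            fr, fc = draw_polygon(rr, cc, shape=(h_px, w_px))
            frames[k, fr, fc] = i + 1
        tracks.append(TrueCell(cell_id=i + 1, areas=np.array(areas), polygons=polys))

    movie = LabelMovie(
        frames, px_size=preset.px_size, dt=preset.dt_as, t0_frame=0, origin=origin
    )
    pulses_true = {
        i + 1: (2 * a, _pulse_count_truth(fm, T, phases[i]))
        for i in range(preset.n_cells)
    }
    truth = GroundTruth(hole=hole, tracks=tracks, pulses_true=pulses_true)
    truth.window_start_s = t_start  # type: ignore[attr-defined]
    return movie, truth


# ---------------------------------------------------------------------------
# filopodia

_STRIPE_WIDTH = 10.0  # µm, engrailed stripe extent along the leading edge
_FILO_RATE = 8.0  # Poisson mean count per stripe
_FILO_SHAPE = 4.0  # Gamma shape of filopodium length
_FILO_MEAN = 3.0  # µm, Gamma mean length


def simulate_filopodia(
    preset: EmbryoPreset, seed: int = 0, rate: float = _FILO_RATE
) -> tuple[dict[int, list[np.ndarray]], dict[int, list[float]]]:
    """Six stripes of filopodia polylines with known counts and lengths.

    Per stripe: count ~ Poisson(rate); lengths ~ Gamma(shape 4, mean 3 µm).
    Returns (stripe -> polylines, stripe -> true lengths).
    """
    rng = np.random.default_rng(seed)
    polylines: dict[int, list[np.ndarray]] = {}
    truth: dict[int, list[float]] = {}
    for stripe in range(1, 7):
        n = rng.poisson(rate)
        stripe_polys, stripe_lengths = [], []
        for _ in range(n):
            length = rng.gamma(_FILO_SHAPE, _FILO_MEAN / _FILO_SHAPE)
            base = np.array(
                [(stripe - 1) * _STRIPE_WIDTH + rng.uniform(0, _STRIPE_WIDTH), 0.0]
            )
            heading = np.pi / 2 + rng.normal(0, 0.3)
            pts = [base]
            seg = length / 3
            for _k in range(3):
                heading += rng.normal(0, 0.2)
                pts.append(pts[-1] + seg * np.array([np.cos(heading), np.sin(heading)]))
            stripe_polys.append(np.array(pts))
            stripe_lengths.append(float(length))
        polylines[stripe] = stripe_polys
        truth[stripe] = stripe_lengths
    return polylines, truth


# ---------------------------------------------------------------------------
# writers


def write_simulation(outdir, preset: EmbryoPreset, hole: HoleSeries,
                     movie: LabelMovie | None = None,
                     truth: GroundTruth | None = None) -> None:
    """Dump a simulation to disk: preset YAML, hole CSV, label TIFF, truth JSON."""
    import json
    from pathlib import Path

    import pandas as pd

    from .movie_io import write_label_movie

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "preset.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "name": preset.name,
                "conv_knots": [list(k) for k in preset.conv_knots],
                "zip_knots": [list(k) for k in preset.zip_knots],
                "duration_min": preset.duration,
                "W0_um": preset.W0,
                "L0_um": preset.L0,
                "n_cells": preset.n_cells,
                "pulse_amp": preset.pulse_amp,
                "pulse_period_s": preset.pulse_period,
                "freq_mult": preset.freq_mult,
                "waviness": preset.waviness,
                "px_size_um": preset.px_size,
                "dt_closure_min": preset.dt_closure,
                "dt_as_s": preset.dt_as,
            },
            fh,
        )
    pd.DataFrame(
        {"t_min": hole.times, "W_um": hole.W, "L_um": hole.L}
    ).to_csv(outdir / "hole.csv", index=False)
    if movie is not None:
        write_label_movie(outdir / "as_sheet.tif", movie)
    if truth is not None:
        payload = {
            "pulses_true": {
                str(k): {"amplitude": v[0], "count": v[1]}
                for k, v in truth.pulses_true.items()
            },
            "cell_areas": {
                str(tc.cell_id): [float(x) for x in tc.areas] for tc in truth.tracks
            },
        }
        if truth.filopodia_true is not None:
            payload["filopodia_true"] = truth.filopodia_true
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)
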