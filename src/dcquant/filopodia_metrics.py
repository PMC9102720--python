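"""Filopodia number and length per engrailed stripe.

Filopodia are consumed as manual polyline annotations (the field measures
them with a line tool), six en-Gal4 stripes per embryo, restricted to the
phase when the two leading edges are 30-50 µm apart.  A filopodium
spanning two stripes is counted in the stripe containing its base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilopodiaSummary",
    "in_measurement_window",
    "polyline_length",
    "filopodia_stats",
    "read_annotations_csv",
    "write_annotations_csv",
]

N_STRIPES = 6
SEPARATION_LO_UM = 30.0
SEPARATION_HI_UM = 50.0


@dataclass
class FilopodiaSummary:
    counts: dict[int, int]  # stripe -> filopodium count
    lengths: dict[int, list[float]]  # stripe -> lengths, µm
    mean_count: float  # per-embryo mean count across the six stripes
    mean_length: float  # mean over all filopodia (nan if none)

    @property
    def all_lengths(self) -> list[float]:
        return [x for ls in self.lengths.values() for x in ls]


def in_measurement_window(W_series, lo: float = SEPARATION_LO_UM,
                          hi: float = SEPARATION_HI_UM) -> np.ndarray:
    """Frames whose leading-edge separation lies in the closed [lo, hi] band."""
    W = np.asarray(W_series, dtype=float)
    frames = np.flatnonzero((W >= lo) & (W <= hi))
    if frames.size == 0:
        raise ValueError(
            f"no frames in separation window [{lo}, {hi}] µm "
            f"(range {W.min():.1f}-{W.max():.1f} µm)"
        )
    return frames


def polyline_length(points) -> float:
    """Sum of Euclidean segment lengths of a polyline."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def filopodia_stats(records: dict[int, list]) -> FilopodiaSummary:
    """Per-stripe counts and lengths, with per-embryo means.

    ``records`` maps stripe id (1-6) to that stripe's polylines; all six
    stripes must be present (an empty stripe is an empty list, counts 0 and
    contributes no lengths).
    """
    if sorted(records) != list(range(1, N_STRIPES + 1)):
        raise ValueError(
            f"expected exactly stripes 1-{N_STRIPES}, got {sorted(records)}"
        )
    counts = {s: len(polys) for s, polys in records.items()}
    lengths = {
        s: [polyline_length(p) for p in polys] for s, polys in records.items()
    }
    all_len = [x for ls in lengths.values() for x in ls]
    return FilopodiaSummary(
        counts=counts,
        lengths=lengths,
        mean_count=float(np.mean(list(counts.values()))),
        mean_length=float(np.mean(all_len)) if all_len else float("nan"),
    )


def write_annotations_csv(path, embryo: str, records: dict[int, list]) -> None:
    rows = []
    for stripe, polys in records.items():
        for fid, pts in enumerate(polys):
            rows.append(
                {
                    "embryo": embryo,
                    "stripe": stripe,
                    "filopodium_id": fid,
                    "vertices": ";".join(f"{x:.4f} {y:.4f}" for x, y in pts),
                }
            )
    pd.DataFrame(rows, columns=["embryo", "stripe", "filopodium_id", "vertices"]).to_csv(
        path, index=False
    )


def read_annotations_csv(path) -> dict[str, dict[int, list]]:
    """Read polyline annotations back into embryo -> stripe -> polylines."""
    df = pd.read_csv(path)
    out: dict[str, dict[int, list]] = {}
    for _, row in df.iterrows():
        pts = np.array(
            [[float(v) for v in p.split()] for p in str(row["vertices"]).split(";")]
        )
        out.setdefault(str(row["embryo"]), {}).setdefault(int(row["stripe"]), []).append(pts)
    for rec in out.values():
        for s in range(1, N_STRIPES + 1):
            rec.setdefault(s, [])
    return out
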