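"""Interpersonal (Delaunay neighbour) distances during the waiting time.

Neighbouring pedestrians are defined through the Delaunay triangulation —
the dual of the Voronoi tessellation — and the lengths of its edges are the
interpersonal distances.  Pooled over all frames of the waiting window they
form the distance histograms; summaries report mean, spread, skewness and
the fraction of distances above a threshold (1.6 m by default, the value
separating standing waiters from slow walkers).

Two small theoretical calculators accompany the measurements: the spacing
of a hypothetical square grid covering the whole available area with n
persons, sqrt(area/n), and the Voronoi density of an interior point of such
a grid, 1/spacing^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.stats import skew

from .trajectory_io import FrameRange, TrajectorySet

__all__ = [
    "DistanceHistogram",
    "DistanceSummary",
    "delaunay_edges",
    "distance_distribution",
    "summarize",
    "grid_spacing",
    "grid_density",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 points, or all points collinear."""


def delaunay_edges(positions, return_pairs: bool = False,
                   max_length: float | None = None):
    """Lengths of the unique Delaunay edges of a point set.

    Convex-hull edges are kept: long edges (1.6-2.5 m) carry meaning as
    slow walkers, so no cut-off is applied unless ``max_length`` is given.
    For co-circular point sets (e.g. the four corners of a square) the
    triangulator picks one of the equally valid diagonals; callers that
    compare edge sets must allow for that tie.
    """
    pts = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"Delaunay triangulation needs >= 3 points, got {len(pts)}"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all points collinear")

    s = tri.simplices
    pairs = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    lengths = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    if max_length is not None:
        keep = lengths <= max_length
        pairs, lengths = pairs[keep], lengths[keep]
    if return_pairs:
        return lengths, pairs
    return lengths


@dataclass
class DistanceHistogram:
    """Binned Delaunay distances pooled over the waiting window."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_edges_total: int
    frames_used: int
    raw: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def distance_distribution(
    ts: TrajectorySet,
    window: FrameRange,
    bin_width: float = 0.1,
    frame_step: int = 1,
    keep_raw: bool = True,
) -> DistanceHistogram:
    """Histogram of Delaunay distances over all frames of the window."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    recs = ts.records
    in_win = (recs["frame"] >= window.start) & (recs["frame"] < window.end)
    if frame_step > 1:
        in_win &= (recs["frame"] - window.start) % frame_step == 0
    sub = recs[in_win]

    all_lengths = []
    frames_used = 0
    for _, frame_recs in sub.groupby("frame"):
        pts = frame_recs[["x", "y"]].to_numpy()
        if len(pts) < 3:
            continue
        try:
            all_lengths.append(delaunay_edges(pts))
        except DegenerateGeometryError:
            continue
        frames_used += 1
    if not all_lengths:
        raise ValueError("no frame in the window has >= 3 triangulable persons")

    lengths = np.concatenate(all_lengths)
    n_bins = int(np.ceil(lengths.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    return DistanceHistogram(
        bin_edges=edges,
        counts=counts,
        n_edges_total=int(lengths.size),
        frames_used=frames_used,
        raw=lengths if keep_raw else None,
    )


@dataclass
class DistanceSummary:
    mean: float
    sd: float
    skewness: float
    fraction_above: dict[float, float]
    n: int
    degenerate: bool = False  # all distances equal; skewness reported as 0


def summarize(data, thresholds=(1.6,)) -> DistanceSummary:
    """Mean, s.d., sample skewness and tail fractions of the distances.

    Accepts raw edge lengths or a DistanceHistogram carrying raw values.
    """
    if isinstance(data, DistanceHistogram):
        if data.raw is None:
            raise ValueError("histogram was built without raw values")
        edges = data.raw
    else:
        edges = np.asarray(data, dtype=float).ravel()
    if edges.size == 0:
        raise ValueError("no distances to summarise")

    sd = float(np.std(edges, ddof=1)) if edges.size > 1 else 0.0
    degenerate = sd == 0.0
    return DistanceSummary(
        mean=float(np.mean(edges)),
        sd=sd,
        skewness=0.0 if degenerate else float(skew(edges, bias=False)),
        fraction_above={float(t): float(np.mean(edges > t)) for t in thresholds},
        n=int(edges.size),
        degenerate=degenerate,
    )


def grid_spacing(area: float, n: int) -> float:
    """Spacing of n persons aligned on a square grid over the full area."""
    if area <= 0:
        raise ValueError("area must be positive")
    if n < 1:
        raise ValueError("need at least one person")
    return float(np.sqrt(area / n))


def grid_density(spacing: float) -> float:
    """Voronoi density of an interior point of a square grid (1/spacing^2)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return float(1.0 / spacing**2)
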