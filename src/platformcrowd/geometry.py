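"""Mock-up railway platform geometry.

The platform is a 7 x 20 m rectangle raised like a real railway platform,
with a tactile safety line 0.8 m from each long (track-facing) edge, a 3 m
wide entrance staircase on one short side, and optionally an obstacle
(information board / elevator mock-up) in the platform centre.

Coordinate frame shared by every module: origin at the platform centre,
long axis x in [-length/2, +length/2] with the entrance at x = +length/2,
cross axis y in [-width/2, +width/2].  The train arrives at one long side;
``arrival_side="lower"`` maps that side to y < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box

__all__ = [
    "Obstacle",
    "PlatformGeometry",
    "Grid",
    "make_platform",
    "signed_safety_distance",
    "in_hazard_zone",
    "GeometryError",
]

#: footprints (extent_along x extent_across, metres) of the two obstacle kinds
OBSTACLE_FOOTPRINTS = {"narrow": (0.6, 3.6), "wide": (3.0, 3.6)}


class GeometryError(ValueError):
    """Invalid geometric configuration or query outside the domain."""


@dataclass(frozen=True)
class Obstacle:
    """Rectangular obstacle on the platform.

    The 3.6 m extent runs across the platform (y), visually separating the
    two track sides; 0.6 m (narrow) or 3 m (wide) run along the platform (x).
    """

    kind: str
    center: tuple[float, float] = (0.0, 0.0)
    extent_along: float = 0.0
    extent_across: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in OBSTACLE_FOOTPRINTS:
            raise GeometryError(f"unknown obstacle kind {self.kind!r}")
        ea, ec = OBSTACLE_FOOTPRINTS[self.kind]
        if self.extent_along == 0.0:
            object.__setattr__(self, "extent_along", ea)
        if self.extent_across == 0.0:
            object.__setattr__(self, "extent_across", ec)

    @property
    def footprint(self) -> Polygon:
        cx, cy = self.center
        return box(
            cx - self.extent_along / 2,
            cy - self.extent_across / 2,
            cx + self.extent_along / 2,
            cy + self.extent_across / 2,
        )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) corner coordinates of the footprint."""
        return self.footprint.bounds


@dataclass(frozen=True)
class PlatformGeometry:
    """Platform rectangle, safety lines, entrance and optional obstacle."""

    length: float = 20.0
    width: float = 7.0
    safety_offset: float = 0.8
    entrance_width: float = 3.0
    arrival_side: str = "lower"
    obstacle: Obstacle | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise GeometryError("platform dimensions must be positive")
        if not 0 < self.safety_offset < self.width / 2:
            raise GeometryError("safety offset must lie within the half-width")
        if not 0 < self.entrance_width <= self.width:
            raise GeometryError("entrance must fit on the short side")
        if self.arrival_side not in ("lower", "upper"):
            raise GeometryError(f"unknown arrival side {self.arrival_side!r}")
        if self.obstacle is not None:
            x1, y1, x2, y2 = self.obstacle.bounds
            half_w = self.width / 2 - self.safety_offset
            if not (
                -self.length / 2 < x1
                and x2 < self.length / 2
                and -half_w < y1
                and y2 < half_w
            ):
                raise GeometryError(
                    "obstacle footprint must lie strictly between the safety lines"
                )

    # -- derived geometry ------------------------------------------------

    @property
    def rectangle(self) -> Polygon:
        return box(-self.length / 2, -self.width / 2, self.length / 2, self.width / 2)

    @property
    def walkable(self) -> Polygon:
        """Platform rectangle minus the obstacle footprint."""
        if self.obstacle is None:
            return self.rectangle
        return self.rectangle.difference(self.obstacle.footprint)

    @property
    def walkable_area(self) -> float:
        return self.walkable.area

    @property
    def entrance_center(self) -> tuple[float, float]:
        """Midpoint of the entrance segment, on the +x short side."""
        return (self.length / 2, 0.0)

    @property
    def safety_line_offset(self) -> float:
        """|y| of the two safety lines."""
        return self.width / 2 - self.safety_offset

    @property
    def arrival_sign(self) -> float:
        """Sign of y on the train-arrival side (-1 for ``lower``)."""
        return -1.0 if self.arrival_side == "lower" else 1.0

    def toward_arrival(self, y):
        """Signed cross-coordinate, positive toward the arrival side."""
        return self.arrival_sign * np.asarray(y, dtype=float)


def make_platform(setup: str = "none") -> PlatformGeometry:
    """Build one of the three experimental set-ups: no / narrow / wide obstacle."""
    if setup == "none":
        return PlatformGeometry()
    if setup in OBSTACLE_FOOTPRINTS:
        return PlatformGeometry(obstacle=Obstacle(kind=setup))
    raise GeometryError(f"unknown setup {setup!r}; expected none, narrow or wide")


def signed_safety_distance(geom: PlatformGeometry, p) -> float:
    """Distance to the nearer safety line, signed toward the interior.

    Positive in the inner platform, zero on a safety line, negative inside
    the 0.8 m hazard band between a safety line and the platform edge.
    Accepts a single (x, y) point or an (n, 2) array; vectorised.
    """
    p = np.asarray(p, dtype=float)
    x, y = p[..., 0], p[..., 1]
    if np.any(np.abs(x) > geom.length / 2) or np.any(np.abs(y) > geom.width / 2):
        raise GeometryError("point outside the platform rectangle")
    d = geom.safety_line_offset - np.abs(y)
    return float(d) if d.ndim == 0 else d


def in_hazard_zone(geom: PlatformGeometry, p) -> bool:
    """True iff p lies strictly inside the hazard band.

    Points exactly on the safety line count as legal (the line itself was
    only rarely crossed; the zero-measure tie is broken toward legal).
    """
    d = signed_safety_distance(geom, p)
    return d < 0 if np.ndim(d) == 0 else np.asarray(d) < 0


@dataclass
class Grid:
    """Square-tile grid covering the platform rectangle.

    ``mask`` is True for cells with positive walkable overlap; values on
    masked-out cells are undefined and written as NaN.
    """

    origin: tuple[float, float]
    resolution: float
    n_along: int
    n_across: int
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_across, n_along): rows are y, columns are x."""
        return (self.n_across, self.n_along)

    @property
    def x_centers(self) -> np.ndarray:
        x0 = self.origin[0]
        return x0 + (np.arange(self.n_along) + 0.5) * self.resolution

    @property
    def y_centers(self) -> np.ndarray:
        y0 = self.origin[1]
        return y0 + (np.arange(self.n_across) + 0.5) * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre coordinates, each of shape ``self.shape``."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def cell_polygons(self) -> np.ndarray:
        """Flat (row-major) array of shapely boxes, one per cell."""
        x0, y0 = self.origin
        r = self.resolution
        polys = np.empty(self.n_across * self.n_along, dtype=object)
        k = 0
        for j in range(self.n_across):
            for i in range(self.n_along):
                polys[k] = box(x0 + i * r, y0 + j * r, x0 + (i + 1) * r, y0 + (j + 1) * r)
                k += 1
        return polys


def make_grid(geom: PlatformGeometry, resolution: float = 0.2) -> Grid:
    """Tile the platform rectangle with square cells of the given side.

    Cell counts are ceilinged so the grid covers the full rectangle; with the
    default 20 x 7 m platform and 0.2 m tiles the tiling is exact (100 x 35).
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    n_along = math.ceil(round(geom.length / resolution, 9))
    n_across = math.ceil(round(geom.width / resolution, 9))
    grid = Grid(
        origin=(-geom.length / 2, -geom.width / 2),
        resolution=resolution,
        n_along=n_along,
        n_across=n_across,
    )
    # mask: keep cells with strictly positive walkable overlap
    areas = shapely.area(shapely.intersection(grid.cell_polygons(), geom.walkable))
    grid.mask = (areas > 1e-12).reshape(grid.shape)
    return grid
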