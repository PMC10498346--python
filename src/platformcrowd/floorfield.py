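"""Static floor field of waiting-place attractiveness.

Five component fields encode the factors that shape where passengers choose
to wait on a platform, each evaluated on the analysis grid:

* ``D`` — entrance proximity: places near the entrance staircase are more
  attractive; the attractiveness falls off as the cube of the normalised
  distance from the far platform end, so mid-platform places stay usable
  while the far end is penalised.
* ``T`` — train-arrival side: a logistic in the cross-coordinate, 0.5 on
  the platform midline and saturating toward the arrival-side track.
* ``E`` — edge safety: a logistic of the signed distance to the nearer
  safety line; exactly 0.5 on the line, below 0.5 inside the 0.8 m hazard
  band, near 1 in the platform middle.
* ``F`` — flow avoidance: a negative Gaussian centred on the entrance, the
  area where a waiting person would stand in everyone's way.
* ``O`` — obstacle: positive (attractive) on the obstacle side facing the
  train arrival, negative (repulsive) behind it where the line of sight to
  the train is blocked, decaying to neutral with distance.

The total attractiveness is the weighted superposition
``A = w1*D + w2*T + w3*E + w4*F + w5*O`` after each component is rescaled
to unit maximum absolute value over walkable cells, so that weights of
order 1-3 compare like with like.  The amplitude/steepness constants a-h
are free positive parameters; the defaults below confine each effect to
the spatial scale its description implies and are overridable throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Grid, PlatformGeometry, make_grid

__all__ = [
    "FieldParams",
    "FieldWeights",
    "FloorField",
    "entrance_proximity",
    "arrival_side",
    "edge_safety",
    "flow_avoidance",
    "obstacle_effect",
    "entrance_proximity_field",
    "arrival_side_field",
    "edge_safety_field",
    "flow_avoidance_field",
    "obstacle_field",
    "compute_components",
    "superpose",
    "DEFAULT_WEIGHTS_OPEN",
    "DEFAULT_WEIGHTS_OBSTACLE",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FieldParams:
    """Positive constants of the component fields.

    a: arrival-side logistic steepness (1/m); T saturates within ~2/a m of
       the midline.
    b: edge-repulsion logistic steepness (1/m); the edge effect is confined
       to ~1/b m around the safety line.
    c, d, e: flow-avoidance Gaussian amplitude (dimensionless) and widths
       along/across (m); defaults match the 3 m entrance.
    f, g, h: obstacle-field amplitude (dimensionless) and decay scales
       along/across (m); ``g``/``h`` default to the obstacle half-extent
       plus 1 m so the influence dies within ~2 m of the footprint.
    """

    a: float = 2.0
    b: float = 3.0
    c: float = 1.0
    d: float = 3.0
    e: float = 3.0
    f: float = 1.0
    g: float | None = None
    h: float | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"field parameter {name} must be positive")
        for name in ("g", "h"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"field parameter {name} must be positive")

    def resolved(self, geom: PlatformGeometry) -> "FieldParams":
        """Fill g/h from the geometry's obstacle when not set explicitly."""
        if self.g is not None and self.h is not None:
            return self
        if geom.obstacle is None:
            return replace(self, g=self.g or 1.0, h=self.h or 1.0)
        g = self.g if self.g is not None else geom.obstacle.extent_along / 2 + 1.0
        h = self.h if self.h is not None else geom.obstacle.extent_across / 2 + 1.0
        return replace(self, g=g, h=h)


@dataclass(frozen=True)
class FieldWeights:
    """Weights of the superposition A = w1*D + w2*T + w3*E + w4*F + w5*O."""

    w1: float = 1.0
    w2: float = 2.0
    w3: float = 3.0
    w4: float = 1.0
    w5: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "w5"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"weight {name} must be finite")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.w1, self.w2, self.w3, self.w4, self.w5)


#: illustrative weight set for the obstacle-free platform
DEFAULT_WEIGHTS_OPEN = FieldWeights(1.0, 2.0, 3.0, 1.0, 0.0)
#: and for a platform with an obstacle (w5 switched on)
DEFAULT_WEIGHTS_OBSTACLE = FieldWeights(1.0, 2.0, 3.0, 1.0, 3.0)

COMPONENT_NAMES = ("D", "T", "E", "F", "O")


@dataclass
class FloorField:
    """Attractiveness values on the analysis grid.

    ``values`` has the grid's (n_across, n_along) shape with NaN on masked
    (non-walkable) cells.  ``components`` optionally retains the normalised
    per-component fields keyed "D", "T", "E", "F", "O".
    """

    grid: Grid
    values: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    weights: FieldWeights | None = None

    def argmax_position(self) -> tuple[float, float]:
        """(x, y) centre of the unmasked cell with the highest value."""
        vals = np.where(self.grid.mask, self.values, -np.inf)
        j, i = np.unravel_index(np.argmax(vals), vals.shape)
        return (float(self.grid.x_centers[i]), float(self.grid.y_centers[j]))


def _masked(grid: Grid, raw: np.ndarray) -> np.ndarray:
    return np.where(grid.mask, raw, np.nan)


# -- continuous evaluators (vectorised over x, y) -----------------------

def entrance_proximity(geom: PlatformGeometry, x) -> np.ndarray:
    """D(x): normalised cubic, 1 at the entrance short side, 0 at the far
    end, varying as the cube of the normalised distance from the far end."""
    x = np.asarray(x, dtype=float)
    x_ent, x_far = geom.length / 2, -geom.length / 2
    t = np.clip((x - x_far) / (x_ent - x_far), 0.0, 1.0)
    return t**3


def arrival_side(geom: PlatformGeometry, y, a: float = 2.0) -> np.ndarray:
    """T(y): logistic in the signed cross-coordinate toward the arrival
    side; 0.5 on the platform midline."""
    if a <= 0:
        raise ValueError("steepness a must be positive")
    s = geom.toward_arrival(y)
    return 1.0 / (1.0 + np.exp(-a * s))


def edge_safety(geom: PlatformGeometry, y, b: float = 3.0) -> np.ndarray:
    """E(y): logistic of the signed safety-line distance; 0.5 on a safety
    line, below 0.5 in the hazard band, near 1 mid-platform."""
    if b <= 0:
        raise ValueError("steepness b must be positive")
    bdist = geom.safety_line_offset - np.abs(np.asarray(y, dtype=float))
    return 1.0 / (1.0 + np.exp(-b * bdist))


def flow_avoidance(geom: PlatformGeometry, x, y,
                   c: float = 1.0, d: float = 3.0, e: float = 3.0) -> np.ndarray:
    """F(x, y): negative Gaussian of depth c centred on the entrance."""
    if min(c, d, e) <= 0:
        raise ValueError("flow-avoidance parameters must be positive")
    x0, y0 = geom.entrance_center
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return -c * np.exp(-((x - x0) ** 2) / d**2 - ((y - y0) ** 2) / e**2)


def obstacle_effect(geom: PlatformGeometry, x, y,
                    f: float = 1.0, g: float | None = None,
                    h: float | None = None) -> np.ndarray:
    """O(x, y): linear-times-Gaussian obstacle field, positive on the
    arrival-facing side, negative behind; zero without an obstacle."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if geom.obstacle is None:
        return np.zeros(np.broadcast(x, y).shape)
    params = FieldParams(f=f, g=g, h=h).resolved(geom)
    x1, y1, x2, y2 = geom.obstacle.bounds
    # signed cross-offset from the obstacle midline, positive toward arrival
    s = geom.toward_arrival(y - (y1 + y2) / 2)
    decay = np.exp(
        -((x - x1) * (x - x2)) / params.g**2 - ((y - y1) * (y - y2)) / params.h**2
    )
    return f * s * decay


# -- grid-evaluated component fields ------------------------------------

def entrance_proximity_field(geom: PlatformGeometry, grid: Grid) -> np.ndarray:
    xx, _ = grid.cell_centers()
    return _masked(grid, entrance_proximity(geom, xx))


def arrival_side_field(geom: PlatformGeometry, grid: Grid, a: float = 2.0) -> np.ndarray:
    _, yy = grid.cell_centers()
    return _masked(grid, arrival_side(geom, yy, a))


def edge_safety_field(geom: PlatformGeometry, grid: Grid, b: float = 3.0) -> np.ndarray:
    _, yy = grid.cell_centers()
    return _masked(grid, edge_safety(geom, yy, b))


def flow_avoidance_field(
    geom: PlatformGeometry, grid: Grid,
    c: float = 1.0, d: float = 3.0, e: float = 3.0,
) -> np.ndarray:
    xx, yy = grid.cell_centers()
    return _masked(grid, flow_avoidance(geom, xx, yy, c, d, e))


def obstacle_field(
    geom: PlatformGeometry, grid: Grid,
    f: float = 1.0, g: float | None = None, h: float | None = None,
) -> np.ndarray:
    """On obstacle-free geometry the component is identically zero
    (logged), so superpositions with w5 != 0 remain well defined."""
    if f <= 0:
        raise ValueError("amplitude f must be positive")
    if geom.obstacle is None:
        log.info("obstacle_field on obstacle-free geometry: returning zeros")
        return _masked(grid, np.zeros(grid.shape))
    xx, yy = grid.cell_centers()
    return _masked(grid, obstacle_effect(geom, xx, yy, f, g, h))


def _normalise(field_vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Rescale to max |value| = 1 over walkable cells (zero field unchanged)."""
    peak = np.nanmax(np.abs(np.where(mask, field_vals, np.nan)))
    if not np.isfinite(peak) or peak == 0:
        return field_vals
    return field_vals / peak


def compute_components(
    geom: PlatformGeometry,
    grid: Grid | None = None,
    params: FieldParams | None = None,
    resolution: float = 0.2,
) -> tuple[Grid, dict[str, np.ndarray]]:
    """Evaluate all five raw component fields on a grid over the geometry."""
    if grid is None:
        grid = make_grid(geom, resolution)
    params = (params or FieldParams()).resolved(geom)
    comps = {
        "D": entrance_proximity_field(geom, grid),
        "T": arrival_side_field(geom, grid, params.a),
        "E": edge_safety_field(geom, grid, params.b),
        "F": flow_avoidance_field(geom, grid, params.c, params.d, params.e),
        "O": obstacle_field(geom, grid, params.f, params.g, params.h),
    }
    return grid, comps


def superpose(
    components: dict[str, np.ndarray],
    weights: FieldWeights,
    grid: Grid,
    normalise: bool = True,
    keep_components: bool = True,
) -> FloorField:
    """Weighted sum of the five components on a common grid.

    Components are first rescaled to unit maximum absolute value over
    walkable cells (the raw fields live on incommensurate scales), unless
    ``normalise=False`` is passed for pre-normalised inputs.
    """
    missing = [k for k in COMPONENT_NAMES if k not in components]
    if missing:
        raise ValueError(f"missing components: {missing}")
    shapes = {components[k].shape for k in COMPONENT_NAMES}
    if shapes != {grid.shape}:
        raise ValueError(f"component grids disagree: {shapes} vs {grid.shape}")

    normed = {
        k: (_normalise(components[k], grid.mask) if normalise else components[k])
        for k in COMPONENT_NAMES
    }
    w = weights.as_tuple()
    total = sum(wi * normed[k] for wi, k in zip(w, COMPONENT_NAMES))
    total = np.where(grid.mask, total, np.nan)
    return FloorField(
        grid=grid,
        values=total,
        components=normed if keep_components else {},
        weights=weights,
    )


def attractiveness_field(
    geom: PlatformGeometry,
    weights: FieldWeights | None = None,
    params: FieldParams | None = None,
    resolution: float = 0.2,
) -> FloorField:
    """One-call convenience: components + superposition with sensible weights.

    Default weights are the illustrative set (1, 2, 3, 1) with the obstacle
    weight switched to 3 when the geometry has an obstacle.
    """
    if weights is None:
        weights = (
            DEFAULT_WEIGHTS_OBSTACLE if geom.obstacle is not None
            else DEFAULT_WEIGHTS_OPEN
        )
    grid, comps = compute_components(geom, params=params, resolution=resolution)
    return superpose(comps, weights, grid)
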