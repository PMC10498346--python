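"""Agent-based generator of platform-waiting trajectories.

Emulates the structure of the mock-up platform experiments so the whole
analysis pipeline can run without the archived recordings: agents enter
one-by-one through the 3 m entrance staircase every 3-5 s, walk to a
waiting position chosen by softmax sampling over the static floor field
(with a crowd-repulsion term keeping a preferred interpersonal spacing and
a hard-core exclusion), then stand with a small low-pass-filtered head
sway for the 2- or 4-minute waiting window.  Standing agents never enter
the 0.8 m hazard band — enforced as a hard constraint, matching the
observation that no participant ever waited there.  Under long (>= 4 min)
waits a fraction of agents abandon their spot and wander slowly on the
sparsely used side of the platform.

Randomness comes from one seed: per-agent substreams are spawned in entry
order, so adding an agent never perturbs earlier agents' draws and equal
seeds give bit-identical trajectory files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.signal import lfilter
from shapely.geometry import LineString, Point

from .floorfield import FieldParams, FloorField, attractiveness_field
from .geometry import GeometryError, PlatformGeometry, make_platform
from .trajectory_io import TrajectorySet

__all__ = ["SimConfig", "CapacityError", "choose_waiting_position", "simulate_run"]

log = logging.getLogger(__name__)


class CapacityError(RuntimeError):
    """No admissible waiting cell left (platform overcrowded)."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated run.

    Defaults mirror the experimental protocol: 40 or 100 agents entering
    every 3-5 s, waiting 2 or 4 min, head sway of a few centimetres, and a
    spacing preference near the observed ~1.1 m interpersonal distance.
    """

    n_agents: int = 40
    setup: str = "none"
    entry_interval: tuple[float, float] = (3.0, 5.0)
    waiting_duration: float = 120.0
    walk_speed: float = 1.0
    sway_sd: float = 0.03
    r_min: float = 0.6
    r_pref: float = 1.1
    repulsion_strength: float = 0.1
    choice_temperature: float = 0.05
    edge_standoff_max: float = 0.5
    p_walk: float = 0.15
    wander_speed: float = 0.5
    seed: int = 0
    frame_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("need at least one agent")
        if not self.r_min < self.r_pref:
            raise ValueError("hard-core radius must be below preferred spacing")
        if self.edge_standoff_max < 0:
            raise ValueError("edge_standoff_max must be non-negative")
        for name in ("waiting_duration", "walk_speed", "sway_sd", "r_min",
                     "r_pref", "choice_temperature", "frame_rate",
                     "wander_speed", "repulsion_strength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.entry_interval
        if not 0 < lo <= hi:
            raise ValueError("entry interval bounds must be positive and ordered")
        if not 0 <= self.p_walk <= 1:
            raise ValueError("p_walk must be a fraction")


# sway is clipped at 3 sigma so placement margins are hard guarantees
SWAY_CLIP_SIGMAS = 3.0


def _admissible_cells(field: FloorField, geom: PlatformGeometry, cfg: SimConfig,
                      standoff: float = 0.0):
    """Flat indices + centre coordinates of cells agents may wait in.

    Cells must be walkable, clear of the hazard band and clear of the
    obstacle with enough margin that any point jittered within the cell,
    plus clipped head sway, stays legal.  ``standoff`` adds an agent's
    personal comfort clearance from the platform boundary (safety lines
    and short-end walls); people line up against edges at individually
    varying distances rather than on a razor-straight line.
    """
    grid = field.grid
    xx, yy = grid.cell_centers()
    half_diag = grid.resolution * np.sqrt(2) / 2
    margin = grid.resolution / 2 + SWAY_CLIP_SIGMAS * cfg.sway_sd
    safety_dist = geom.safety_line_offset - np.abs(yy)
    end_dist = geom.length / 2 - np.abs(xx)
    ok = grid.mask & (safety_dist >= margin + standoff) & (end_dist >= margin + standoff)
    if geom.obstacle is not None:
        inflated = geom.obstacle.footprint.buffer(half_diag + SWAY_CLIP_SIGMAS * cfg.sway_sd)
        inside = shapely.contains_xy(inflated, xx.ravel(), yy.ravel()).reshape(xx.shape)
        ok &= ~inside
    idx = np.flatnonzero(ok.ravel())
    centers = np.column_stack([xx.ravel()[idx], yy.ravel()[idx]])
    return idx, centers


def choose_waiting_position(
    field: FloorField,
    occupied: list | np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Sample one waiting position from the floor field and the crowd.

    Score of a cell = field value − sum over occupants of
    kappa * exp(−(r / r_pref)^2).  One candidate point is drawn per cell
    (uniform jitter within the cell); candidates whose distance to any
    occupant, less the clipped-sway headroom of both heads, would dip
    below the hard-core radius are excluded outright.  A cell is then
    drawn with probability ∝ exp(score / temperature) and its candidate
    point returned.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geom = _geom_for(cfg)
    standoff = rng.uniform(0.0, cfg.edge_standoff_max)
    occ = np.asarray(occupied, dtype=float).reshape(-1, 2)
    sway_margin = 2 * SWAY_CLIP_SIGMAS * cfg.sway_sd

    candidates = scores = None
    # graded fallback keeps the outer shell ragged even when crowded out
    for so in (standoff, standoff / 2, standoff / 4, 0.0):
        idx, centers = _admissible_cells(field, geom, cfg, standoff=so)
        if len(idx) == 0:
            continue
        half = field.grid.resolution / 2
        cand = centers + rng.uniform(-half, half, size=centers.shape)
        sc = field.values.ravel()[idx].copy()
        if len(occ):
            d = np.linalg.norm(cand[:, None, :] - occ[None, :, :], axis=-1)
            feasible = np.all(d >= cfg.r_min + sway_margin, axis=1)
            if not feasible.any():
                continue
            penalty = cfg.repulsion_strength * np.sum(
                np.exp(-((d / cfg.r_pref) ** 2)), axis=1
            )
            cand, sc = cand[feasible], sc[feasible] - penalty[feasible]
        candidates, scores = cand, sc
        break
    if candidates is None:
        raise CapacityError(f"no admissible waiting cell for {len(occ)} occupants")

    logits = (scores - scores.max()) / cfg.choice_temperature
    probs = np.exp(logits)
    probs /= probs.sum()
    k = rng.choice(len(scores), p=probs)
    return (float(candidates[k, 0]), float(candidates[k, 1]))


def _geom_for(cfg: SimConfig) -> PlatformGeometry:
    return make_platform(cfg.setup)


def _route(geom: PlatformGeometry, start, goal) -> list[tuple[float, float]]:
    """Waypoint path from start to goal, detouring around the obstacle.

    A single intermediate waypoint at the nearest obstacle corner, inflated
    by 0.3 m, suffices on this convex-obstacle platform.
    """
    if geom.obstacle is None:
        return [start, goal]
    blocked = geom.obstacle.footprint.buffer(0.05)
    if not LineString([start, goal]).intersects(blocked):
        return [start, goal]
    corners = np.asarray(
        geom.obstacle.footprint.buffer(0.3, join_style="mitre").exterior.coords[:-1]
    )
    dists = (
        np.linalg.norm(corners - np.asarray(start), axis=1)
        + np.linalg.norm(corners - np.asarray(goal), axis=1)
    )
    order = np.argsort(dists)
    for k in order:
        wp = tuple(corners[k])
        if not LineString([start, wp]).intersects(blocked) and not LineString(
            [wp, goal]
        ).intersects(blocked):
            return [start, wp, goal]
    # two-corner detour: consecutive inflated corners around the footprint
    n = len(corners)
    best = None
    for i in range(n):
        for j in (i - 1, i + 1):
            w1, w2 = tuple(corners[i]), tuple(corners[j % n])
            legs = [LineString([start, w1]), LineString([w1, w2]), LineString([w2, goal])]
            if any(leg.intersects(blocked) for leg in legs):
                continue
            total = sum(leg.length for leg in legs)
            if best is None or total < best[0]:
                best = (total, [start, w1, w2, goal])
    if best is not None:
        return best[1]
    raise GeometryError("no collision-free path around the obstacle")


def _walk_frames(path, speed, frame_rate) -> np.ndarray:
    """Positions sampled at the frame rate while walking the waypoint path."""
    pts = np.asarray(path, dtype=float)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg_len.sum()
    n_frames = int(np.ceil(total / speed * frame_rate))
    if n_frames == 0:
        return pts[-1:].copy()
    s = np.linspace(0, total, n_frames, endpoint=False) + total / n_frames
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty((n_frames, 2))
    for i, si in enumerate(s):
        j = min(np.searchsorted(cum, si, side="right") - 1, len(seg_len) - 1)
        f = (si - cum[j]) / seg_len[j] if seg_len[j] > 0 else 1.0
        out[i] = pts[j] + f * (pts[j + 1] - pts[j])
    return out


def _sway(n_frames: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered Gaussian head sway, clipped at 3 sigma.

    AR(1) with phi = 0.95 and stationary s.d. ``sd`` — slow wobble around
    the waiting spot rather than frame-to-frame jitter.
    """
    if n_frames == 0:
        return np.empty((0, 2))
    phi = 0.95
    eps = rng.normal(scale=sd * np.sqrt(1 - phi**2), size=(n_frames, 2))
    prev = rng.normal(scale=sd, size=2)
    out, _ = lfilter([1.0], [1.0, -phi], eps, axis=0, zi=(phi * prev)[None, :])
    np.clip(out, -SWAY_CLIP_SIGMAS * sd, SWAY_CLIP_SIGMAS * sd, out=out)
    return out


def _wander_track(
    geom: PlatformGeometry,
    cfg: SimConfig,
    start: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow wandering between random waypoints on the non-arrival side.

    A stand-in for the wave-like walker trajectories seen under long waits;
    waypoints keep clear of the hazard band and the obstacle.
    """
    if n_frames == 0:
        return np.empty((0, 2))
    margin = 0.5
    y_lo_abs, y_hi_abs = margin, geom.safety_line_offset - margin
    sgn = -geom.arrival_sign  # opposite of arrival side
    pos = np.asarray(start, dtype=float)
    frames: list[np.ndarray] = []
    while sum(len(f) for f in frames) < n_frames:
        for _ in range(100):
            wx = rng.uniform(-geom.length / 2 + margin, geom.length / 2 - margin)
            wy = sgn * rng.uniform(y_lo_abs, y_hi_abs)
            if geom.obstacle is None or not geom.obstacle.footprint.buffer(0.4).contains(
                Point(wx, wy)
            ):
                break
        leg = _walk_frames(_route(geom, tuple(pos), (wx, wy)), cfg.wander_speed,
                           cfg.frame_rate)
        frames.append(leg)
        pos = leg[-1]
        # brief pause at each waypoint
        pause = int(rng.uniform(1.0, 4.0) * cfg.frame_rate)
        frames.append(np.tile(pos, (pause, 1)))
    return np.vstack(frames)[:n_frames]


def simulate_run(cfg: SimConfig,
                 field: FloorField | None = None) -> TrajectorySet:
    """Simulate one experimental run and return its trajectory set.

    The floor field defaults to the geometry-appropriate superposition
    (obstacle weight on iff an obstacle is present).  The run covers the
    filling phase plus the waiting window; the waiting window extracted
    from the output therefore has the configured duration exactly.
    """
    geom = _geom_for(cfg)
    if field is None:
        field = attractiveness_field(geom, params=FieldParams())

    ss = np.random.SeedSequence(cfg.seed)
    agent_seeds = ss.spawn(cfg.n_agents)

    # entry schedule: agent i enters at the cumulative sum of its own draw,
    # so earlier agents' streams are untouched when n_agents grows
    entry_times = np.empty(cfg.n_agents)
    rngs = []
    t = 0.0
    for i in range(cfg.n_agents):
        rng = np.random.default_rng(agent_seeds[i])
        rngs.append(rng)
        gap = rng.uniform(*cfg.entry_interval) if i > 0 else 0.0
        t += gap
        entry_times[i] = t

    last_entry_frame = int(round(entry_times[-1] * cfg.frame_rate))
    end_frame = last_entry_frame + int(round(cfg.waiting_duration * cfg.frame_rate))

    is_walker = np.array(
        [cfg.waiting_duration >= 240.0 and rngs[i].uniform() < cfg.p_walk
         for i in range(cfg.n_agents)]
    )

    occupied: list[tuple[float, float]] = []
    all_ids, all_frames, all_x, all_y = [], [], [], []
    entrance = geom.entrance_center
    # nudge the spawn point just inside the rectangle
    spawn = (entrance[0] - 1e-3, entrance[1])

    for i in range(cfg.n_agents):
        rng = rngs[i]
        target = choose_waiting_position(field, occupied, cfg, rng)
        entry_frame = int(round(entry_times[i] * cfg.frame_rate))
        walk = _walk_frames(_route(geom, spawn, target), cfg.walk_speed,
                            cfg.frame_rate)
        arrive_frame = entry_frame + len(walk)
        n_stand = max(end_frame - arrive_frame, 0)

        if is_walker[i]:
            # stand for a random while, then abandon the spot and wander
            stand_s = rng.uniform(10.0, cfg.waiting_duration / 2)
            n_keep = min(int(stand_s * cfg.frame_rate), n_stand)
            sway = _sway(n_keep, cfg.sway_sd, rng)
            standing = np.asarray(target) + sway
            wander = _wander_track(geom, cfg, standing[-1] if n_keep else target,
                                   n_stand - n_keep, rng)
            track = np.vstack([walk, standing, wander])
        else:
            sway = _sway(n_stand, cfg.sway_sd, rng)
            track = np.vstack([walk, np.asarray(target) + sway])
            occupied.append(target)

        frames = entry_frame + np.arange(len(track))
        keep = frames < end_frame
        all_ids.append(np.full(keep.sum(), i + 1))
        all_frames.append(frames[keep])
        all_x.append(track[keep, 0])
        all_y.append(track[keep, 1])

    records = pd.DataFrame(
        {
            "person_id": np.concatenate(all_ids),
            "frame": np.concatenate(all_frames),
            "x": np.concatenate(all_x),
            "y": np.concatenate(all_y),
        }
    )
    return TrajectorySet(records=records, frame_rate=cfg.frame_rate)


def preset_config(name: str, seed: int = 0) -> SimConfig:
    """Named run presets: '<setup>-<N>-<minutes>min', e.g. 'none-40-2min'."""
    try:
        setup, n, dur = name.split("-")
        cfg = SimConfig(
            n_agents=int(n),
            setup=setup,
            waiting_duration=float(dur.rstrip("min")) * 60.0,
            seed=seed,
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed preset name {name!r}") from exc
    return cfg
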