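"""Reading, writing and windowing of head-trajectory files.

The on-disk dialect is the common plain-text export of overhead tracking
software: one row per person per frame with whitespace-separated columns

    person_id  frame  x[m]  y[m]  [z ...]

``#``-prefixed lines are comments; columns beyond the fourth are ignored
(the analysis is planar).  The default frame rate is 50 frames per second.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "FrameRange",
    "read_trajectories",
    "write_trajectories",
    "waiting_window",
    "positions_at_frame",
    "TrajectoryParseError",
]

log = logging.getLogger(__name__)

COLUMNS = ["person_id", "frame", "x", "y"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file."""


@dataclass
class TrajectorySet:
    """All agents' timestamped head positions for one run.

    ``records`` is a DataFrame with columns person_id, frame (ints) and
    x, y (metres), sorted by (person_id, frame) with unique index pairs.
    """

    records: pd.DataFrame
    frame_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dup = self.records.duplicated(subset=["person_id", "frame"])
        if dup.any():
            bad = self.records.loc[dup.idxmax()]
            raise TrajectoryParseError(
                f"duplicate (person_id, frame) pair "
                f"({int(bad.person_id)}, {int(bad.frame)})"
            )
        self.records = (
            self.records.sort_values(["person_id", "frame"])
            .reset_index(drop=True)
            .astype({"person_id": np.int64, "frame": np.int64})
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_persons(self) -> int:
        return self.records["person_id"].nunique()

    @property
    def frame_range(self) -> tuple[int, int]:
        f = self.records["frame"]
        return int(f.min()), int(f.max())

    def entry_frames(self) -> pd.Series:
        """First frame of each person, indexed by person_id."""
        return self.records.groupby("person_id")["frame"].min()


@dataclass(frozen=True)
class FrameRange:
    """Half-open frame interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty frame range [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def frames(self, step: int = 1) -> np.ndarray:
        return np.arange(self.start, self.end, step)


def read_trajectories(source, frame_rate: float = 50.0) -> TrajectorySet:
    """Parse a trajectory file (path, string content, or text stream)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            return read_trajectories(fh, frame_rate)
    if isinstance(source, str):
        source = io.StringIO(source)

    ids, frames, xs, ys = [], [], [], []
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 4:
            raise TrajectoryParseError(
                f"line {lineno}: expected at least 4 columns, got {len(parts)}"
            )
        try:
            pid, fr = int(parts[0]), int(parts[1])
            x, y = float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise TrajectoryParseError(f"line {lineno}: non-numeric field ({exc})") from exc
        ids.append(pid)
        frames.append(fr)
        xs.append(x)
        ys.append(y)

    records = pd.DataFrame({"person_id": ids, "frame": frames, "x": xs, "y": ys})
    return TrajectorySet(records=records, frame_rate=frame_rate)


def write_trajectories(ts: TrajectorySet, target) -> None:
    """Write in the same dialect (positions at 6 decimals; round-trip safe)."""
    def _write(fh) -> None:
        fh.write(f"# framerate: {ts.frame_rate:g} fps\n")
        fh.write("# id frame x/m y/m\n")
        for row in ts.records.itertuples(index=False):
            fh.write(f"{row.person_id} {row.frame} {row.x:.6f} {row.y:.6f}\n")

    if isinstance(target, (str, Path)):
        with open(target, "w") as fh:
            _write(fh)
    else:
        _write(target)


def waiting_window(ts: TrajectorySet, duration_s: float) -> FrameRange:
    """Frame window of the waiting time.

    The window starts once the last person has entered the platform and
    nominally lasts ``duration_s``; if the recording is shorter, the end is
    clipped to the last frame present (with a warning) so truncated runs
    remain analysable.
    """
    if len(ts) == 0:
        raise ValueError("empty trajectory set")
    if duration_s <= 0:
        raise ValueError("waiting duration must be positive")
    start = int(ts.entry_frames().max())
    nominal_end = start + int(round(duration_s * ts.frame_rate))
    last = ts.frame_range[1]
    end = min(nominal_end, last + 1)
    if end < nominal_end:
        warnings.warn(
            f"recording ends at frame {last}; waiting window clipped to "
            f"[{start}, {end}) instead of [{start}, {nominal_end})",
            stacklevel=2,
        )
    return FrameRange(start, end)


def positions_at_frame(ts: TrajectorySet, frame: int) -> list[tuple[int, tuple[float, float]]]:
    """(person_id, (x, y)) for every person present at the given frame."""
    sel = ts.records[ts.records["frame"] == frame]
    return [(int(r.person_id), (r.x, r.y)) for r in sel.itertuples(index=False)]


def position_array_at_frame(ts: TrajectorySet, frame: int) -> np.ndarray:
    """(n, 2) array of positions at a frame (order: ascending person_id)."""
    sel = ts.records[ts.records["frame"] == frame]
    return sel[["x", "y"]].to_numpy(dtype=float)
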