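"""Plain-text serialisation of gridded fields (density profiles, floor fields).

Format: four '#'-prefixed header lines (origin, resolution, n_along,
n_across) followed by row-major values, one grid row per line, masked
cells written as ``nan``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Grid

__all__ = ["write_grid_values", "read_grid_values"]


def write_grid_values(grid: Grid, values: np.ndarray, path) -> None:
    vals = np.asarray(values, dtype=float).reshape(grid.shape)
    with open(path, "w") as fh:
        fh.write(f"# origin: {grid.origin[0]:.6f} {grid.origin[1]:.6f}\n")
        fh.write(f"# resolution: {grid.resolution:.6f}\n")
        fh.write(f"# n_along: {grid.n_along}\n")
        fh.write(f"# n_across: {grid.n_across}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_grid_values(path) -> tuple[Grid, np.ndarray]:
    lines = Path(path).read_text().splitlines()
    header = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, rest = line.lstrip("# ").partition(":")
        header[key.strip()] = rest.split()
    origin = tuple(float(v) for v in header["origin"])
    resolution = float(header["resolution"][0])
    n_along = int(header["n_along"][0])
    n_across = int(header["n_across"][0])
    values = np.loadtxt(lines[body_start:], ndmin=2)
    if values.shape != (n_across, n_along):
        raise ValueError(
            f"grid body shape {values.shape} does not match header "
            f"({n_across}, {n_along})"
        )
    grid = Grid(origin=origin, resolution=resolution, n_along=n_along,
                n_across=n_across, mask=~np.isnan(values))
    return grid, values
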