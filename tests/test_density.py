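import numpy as np
import pytest
import shapely

from platformcrowd.density import (
    DensityProfile,
    density_at_points,
    marginal_density,
    tile_profile,
    voronoi_cells,
    voronoi_frame,
)
from platformcrowd.geometry import make_grid
from platformcrowd.trajectory_io import FrameRange

from conftest import make_static_ts


def test_single_agent_owns_whole_platform(platform):
    vf = voronoi_frame([(1.0, 0.5)], platform)
    assert vf.areas[0] == pytest.approx(140.0, rel=1e-9)
    assert vf.densities[0] == pytest.approx(1 / 140.0, rel=1e-9)


def test_mirror_symmetric_pair_splits_evenly(platform):
    vf = voronoi_frame([(-2.0, 1.0), (2.0, -1.0)], platform)
    assert vf.areas == pytest.approx([70.0, 70.0], rel=1e-9)


def test_square_lattice_interior_cell_density(platform):
    # 9 x 5 lattice at 1.2 m spacing: the central point's cell is the
    # 1.2 x 1.2 m square, density 1/1.44 ~ 0.69 per m^2
    xs, ys = np.arange(-4, 5) * 1.2, np.arange(-2, 3) * 1.2
    pts = np.array([(x, y) for x in xs for y in ys])
    vf = voronoi_frame(pts, platform)
    center = int(np.argmin(np.sum(pts**2, axis=1)))
    assert vf.densities[center] == pytest.approx(1 / 1.44, rel=1e-9)


def test_degenerate_inputs_rejected(platform):
    with pytest.raises(ValueError, match="at least one"):
        voronoi_frame(np.empty((0, 2)), platform)
    with pytest.raises(ValueError, match="coincident"):
        voronoi_frame([(0.0, 0.0), (0.0, 0.0)], platform)


def test_collinear_points_still_tessellate(platform):
    # exactly collinear agents: deterministic jitter rescue keeps the
    # tessellation conservative
    pts = np.column_stack([np.linspace(-6, 6, 5), np.zeros(5)])
    vf = voronoi_frame(pts, platform)
    assert vf.areas.sum() == pytest.approx(140.0, rel=1e-6)


@pytest.mark.parametrize("setup", ["none", "narrow", "wide"])
def test_cell_areas_sum_to_walkable_area(setup, request):
    geom = request.getfixturevalue(
        {"none": "platform", "narrow": "platform_narrow", "wide": "platform_wide"}[setup]
    )
    rng = np.random.default_rng(11)
    pts = []
    while len(pts) < 20:
        p = rng.uniform([-9.8, -3.4], [9.8, 3.4])
        if shapely.contains_xy(geom.walkable, p[0], p[1]):
            pts.append(p)
    vf = voronoi_frame(np.array(pts), geom)
    assert vf.areas.sum() == pytest.approx(geom.walkable_area, rel=1e-6)
    # pairwise interior-disjoint: sum of pairwise overlaps vanishes
    inter = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            inter += vf.cells[i].intersection(vf.cells[j]).area
    assert inter < 1e-9


def test_removing_far_agent_keeps_shielded_cell(platform):
    # an agent strictly between two others shields the near cell from the
    # far agent entirely
    with_far = voronoi_cells(np.array([[-8.0, 0.0], [0.0, 0.0], [8.0, 0.0]]), platform)
    without = voronoi_cells(np.array([[-8.0, 0.0], [0.0, 0.0]]), platform)
    assert with_far[0].symmetric_difference(without[0]).area < 1e-9


def test_profile_of_static_agents_conserves_person_count(platform):
    ts = make_static_ts([(1.0, -1.0)], n_frames=10)
    prof = tile_profile(ts, FrameRange(0, 10), platform)
    assert prof.integral() == pytest.approx(1.0, rel=1e-6)

    ts5 = make_static_ts(
        [(-3.0, 1.2), (2.5, -1.0), (0.0, 0.3), (6.0, 2.0), (-7.0, -2.0)], n_frames=3
    )
    prof5 = tile_profile(ts5, FrameRange(0, 3), platform)
    assert prof5.integral() == pytest.approx(5.0, rel=1e-6)


def test_tile_values_match_point_sampling_oracle(platform, five_agent_points):
    """Tile averages agree with brute-force Monte-Carlo sampling of the
    piecewise-constant density field to within 1 %."""
    ts = make_static_ts(five_agent_points, n_frames=1)
    prof = tile_profile(ts, FrameRange(0, 1), platform)
    grid = prof.grid
    rng = np.random.default_rng(0)
    # probe tiles spread over the platform, including cell-boundary tiles
    probes = [(10, 30), (17, 50), (25, 40), (5, 80), (30, 20), (0, 0), (34, 99),
              (17, 62), (8, 55)]
    for j, i in probes:
        x0 = grid.origin[0] + i * grid.resolution
        y0 = grid.origin[1] + j * grid.resolution
        pts = np.column_stack(
            [rng.uniform(x0, x0 + grid.resolution, 60000),
             rng.uniform(y0, y0 + grid.resolution, 60000)]
        )
        mc = np.nanmean(density_at_points(pts, five_agent_points, platform))
        assert prof.values[j, i] == pytest.approx(mc, rel=0.01)


def test_empty_window_rejected(platform):
    ts = make_static_ts([(0.0, 0.0)], n_frames=5)
    with pytest.raises(ValueError, match="window"):
        tile_profile(ts, FrameRange(100, 110), platform)


def _uniform_profile(platform, value=0.5):
    grid = make_grid(platform, 0.2)
    vals = np.full(grid.shape, value)
    walk = np.full(grid.shape, 0.04)
    return DensityProfile(grid=grid, values=vals, frames_used=1,
                          tile_walkable_area=walk)


def test_marginal_of_uniform_profile_has_zero_deviation(platform):
    curve = marginal_density(_uniform_profile(platform), "along", "lower")
    assert curve.mean_density == pytest.approx(np.full(100, 0.5))
    assert curve.deviation == pytest.approx(np.zeros(100), abs=1e-12)
    assert curve.overall_mean == pytest.approx(0.5)


def test_marginal_sides_separate_occupancy(platform):
    # all agents on the lower side: the upper-side curve stays far below
    ts = make_static_ts([(4.0, -2.0), (0.0, -1.5), (-4.0, -2.2), (6.0, -1.0)],
                        n_frames=2)
    prof = tile_profile(ts, FrameRange(0, 2), platform)
    lower = marginal_density(prof, "along", "lower")
    upper = marginal_density(prof, "along", "upper")
    # Voronoi cells of lower-side agents still cover the upper half, so the
    # upper curve is not zero, but it must stay clearly below the lower one
    assert upper.overall_mean < lower.overall_mean


def test_marginal_deviation_tracks_entrance_cluster(platform):
    # cluster near the entrance (x > 0): positive deviation there,
    # negative at the far side
    ts = make_static_ts([(8.0, -1.0), (7.0, -2.0), (8.5, -2.2), (7.5, -0.5)],
                        n_frames=1)
    prof = tile_profile(ts, FrameRange(0, 1), platform)
    curve = marginal_density(prof, "along", "lower")
    near = curve.deviation[curve.positions > 7]
    far = curve.deviation[curve.positions < -7]
    assert near.mean() > 0
    assert far.mean() < 0


def test_marginal_rejects_empty_side(platform):
    prof = _uniform_profile(platform)
    prof.grid.mask = prof.grid.mask.copy()
    prof.grid.mask[:18, :] = False  # strip out the whole lower half
    with pytest.raises(ValueError, match="no accessible tiles"):
        marginal_density(prof, "along", "lower")
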