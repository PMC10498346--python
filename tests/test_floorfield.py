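import numpy as np
import pytest

from platformcrowd.floorfield import (
    FieldParams,
    FieldWeights,
    arrival_side,
    attractiveness_field,
    compute_components,
    edge_safety,
    entrance_proximity,
    flow_avoidance,
    obstacle_effect,
    obstacle_field,
    superpose,
)
from platformcrowd.geometry import make_grid


def test_entrance_proximity_profile(platform):
    assert entrance_proximity(platform, 10.0) == pytest.approx(1.0)
    assert entrance_proximity(platform, -10.0) == pytest.approx(0.0)
    assert entrance_proximity(platform, 0.0) == pytest.approx(0.125)
    # non-increasing with distance from the entrance
    x = np.linspace(-10, 10, 201)
    assert np.all(np.diff(entrance_proximity(platform, x)) >= 0)


def test_arrival_side_logistic(platform):
    assert arrival_side(platform, 0.0) == pytest.approx(0.5)
    # 2 m into the arrival (lower) side with a = 2
    assert arrival_side(platform, -2.0, a=2.0) == pytest.approx(
        1 / (1 + np.exp(-4)), rel=1e-9
    )
    s = np.linspace(-3.5, 3.5, 50)
    assert arrival_side(platform, s) + arrival_side(platform, -s) == pytest.approx(
        np.ones(50)
    )
    # strictly increasing toward the arrival side (decreasing in y here)
    assert np.all(np.diff(arrival_side(platform, s)) < 0)
    with pytest.raises(ValueError):
        arrival_side(platform, 0.0, a=-1.0)


def test_edge_safety_logistic(platform):
    assert edge_safety(platform, 2.7) == pytest.approx(0.5)
    assert edge_safety(platform, 0.0, b=3.0) == pytest.approx(
        1 / (1 + np.exp(-8.1)), rel=1e-9
    )
    assert edge_safety(platform, 3.5, b=3.0) == pytest.approx(
        1 / (1 + np.exp(2.4)), rel=1e-9
    )
    # hazard band scores below one half
    assert edge_safety(platform, -3.0) < 0.5


def test_flow_avoidance_gaussian(platform):
    x0, y0 = platform.entrance_center
    assert flow_avoidance(platform, x0, y0, c=1.0) == pytest.approx(-1.0)
    assert flow_avoidance(platform, x0 - 3.0, y0, c=1.0, d=3.0) == pytest.approx(
        -np.exp(-1)
    )
    # mirror symmetry across the entrance axis
    assert flow_avoidance(platform, 5.0, 1.3) == pytest.approx(
        flow_avoidance(platform, 5.0, -1.3)
    )
    assert np.all(flow_avoidance(platform, np.linspace(-10, 10, 30), 0.0) <= 0)


def test_obstacle_effect_orientation(platform, platform_narrow):
    assert obstacle_effect(platform, 1.0, 1.0) == 0.0
    # antisymmetric about the obstacle midline
    y = np.linspace(0.1, 2.4, 20)
    front = obstacle_effect(platform_narrow, 0.0, -y)  # arrival side
    back = obstacle_effect(platform_narrow, 0.0, y)
    assert front == pytest.approx(-back)
    assert np.all(front > 0)
    assert obstacle_effect(platform_narrow, 5.0, 0.0) == pytest.approx(0.0)


def test_obstacle_field_zero_without_obstacle(platform):
    grid = make_grid(platform)
    vals = obstacle_field(platform, grid)
    assert np.nansum(np.abs(vals)) == 0.0


def test_field_params_validation(platform_narrow):
    with pytest.raises(ValueError):
        FieldParams(a=0.0)
    p = FieldParams().resolved(platform_narrow)
    assert p.g == pytest.approx(0.3 + 1.0)
    assert p.h == pytest.approx(1.8 + 1.0)


def test_superpose_weights_and_linearity(platform):
    grid, comps = compute_components(platform)
    zero = superpose(comps, FieldWeights(0, 0, 0, 0, 0), grid)
    assert np.nansum(np.abs(zero.values)) == 0.0

    w1 = superpose(comps, FieldWeights(1, 1, 1, 1, 0), grid)
    w2 = superpose(comps, FieldWeights(1, 2, 1, 1, 0), grid)
    extra = w2.values - w1.values
    assert extra == pytest.approx(w1.components["T"], nan_ok=True)

    for name, comp in w1.components.items():
        peak = np.nanmax(np.abs(comp))
        assert peak <= 1.0 + 1e-12, name


def test_superpose_rejects_grid_mismatch(platform):
    grid, comps = compute_components(platform)
    small_grid, small_comps = compute_components(platform, resolution=0.5)
    mixed = dict(comps, O=small_comps["O"])
    with pytest.raises(ValueError, match="grids disagree"):
        superpose(mixed, FieldWeights(), grid)


def test_hot_zone_on_arrival_side(platform):
    """Weighted superposition (1,2,3,1,0): the most attractive cell sits on
    the arrival side, in the entrance-proximal half, clear of the hazard."""
    ff = attractiveness_field(platform, weights=FieldWeights(1, 2, 3, 1, 0))
    x, y = ff.argmax_position()
    assert y < 0                                    # arrival side
    assert x > 0                                    # entrance-proximal half
    assert abs(y) < platform.safety_line_offset     # outside hazard band


def test_obstacle_shadow_scores_below_front(platform_narrow):
    """With the narrow obstacle and weights (1,2,3,1,3), cells directly
    behind the obstacle score below their arrival-side counterparts."""
    ff = attractiveness_field(platform_narrow, weights=FieldWeights(1, 2, 3, 1, 3))
    xx, yy = ff.grid.cell_centers()
    x1, y1, x2, y2 = platform_narrow.obstacle.bounds
    col = (xx > x1) & (xx < x2)
    behind = col & (yy > y2) & (yy < y2 + 1.0)
    front = col & (yy < y1) & (yy > y1 - 1.0)
    assert np.nanmean(ff.values[behind]) < np.nanmean(ff.values[front])
    # arrival side beats the opposite side on average
    assert np.nanmean(ff.values[ff.grid.mask & (yy < 0)]) > np.nanmean(
        ff.values[ff.grid.mask & (yy > 0)]
    )
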