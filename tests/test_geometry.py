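"""Phantom geometry: builders, layer queries, normals, depth maps."""

import numpy as np
import pytest

from curvedr.geometry import (
    SurfaceField,
    build_flat_surface,
    build_layered_model,
    build_spherical_cap_surface,
    build_wedge_surface,
    build_wound_surface,
    depth_map,
    medium_at,
    surface_normals,
)
from curvedr.optics import LayerSpec, OpticalProperties, skin_layers


def test_skin_stack_thickness_and_layer_lookup():
    model = build_layered_model(build_flat_surface(0.1), skin_layers())
    assert np.isclose(model.boundaries[-1], 4.0)
    # above the surface -> ambient air
    assert medium_at(model, (5.0, 5.0, 0.5)) == "ambient"
    # just below the surface -> epidermis; exactly at the surface too
    assert medium_at(model, (5.0, 5.0, -0.01)) == "epidermis"
    assert medium_at(model, (5.0, 5.0, 0.0)) == "epidermis"
    # 0.1 cm deep -> dermis (epidermis spans only 0.0206 cm)
    assert medium_at(model, (5.0, 5.0, -0.1)) == "dermis"
    assert medium_at(model, (5.0, 5.0, -1.0)) == "subcutis"
    # below the 4 cm stack -> ambient again
    assert medium_at(model, (5.0, 5.0, -4.5)) == "ambient"


def test_medium_labels_monotone_with_depth():
    model = build_layered_model(build_flat_surface(0.1), skin_layers())
    order = {"epidermis": 0, "dermis": 1, "subcutis": 2, "ambient": 3}
    labels = [medium_at(model, (3.3, 7.1, -z)) for z in np.linspace(0, 4.2, 60)]
    ranks = [order[l] for l in labels]
    assert ranks == sorted(ranks)


def test_layer_validation_errors():
    thick = LayerSpec(
        "too_thick",
        7.0,
        {690: OpticalProperties(1, 1, 0, 1.4), 830: OpticalProperties(1, 1, 0, 1.4)},
    )
    with pytest.raises(ValueError):
        build_layered_model(build_flat_surface(0.1), [thick])
    missing = LayerSpec("only690", 1.0, {690: OpticalProperties(1, 1, 0, 1.4)})
    with pytest.raises(ValueError):
        build_layered_model(build_flat_surface(0.1), [missing])


def test_flat_surface_properties():
    surf = build_flat_surface(0.05)
    assert surf.shape == (200, 200)
    assert np.all(surf.heights == 0)
    nm = surface_normals(surf)
    assert np.allclose(nm.cos_theta, 1.0)
    assert np.allclose(depth_map(surf, 0.0).delta_z, 0.0)


@pytest.mark.parametrize(
    "radius,expected_apex",
    [(2.5, 2.5), (3.5, 3.5 - np.sqrt(3.5**2 - 2.5**2))],
)
def test_cap_apex_height(radius, expected_apex):
    surf = build_spherical_cap_surface(radius, "convex", 5.0, pitch=0.05)
    assert np.isclose(surf.heights.max(), expected_apex, atol=2e-3)


def test_cap_rim_continuity_and_concave_sign():
    surf = build_spherical_cap_surface(2.5, "concave", 5.0, pitch=0.05)
    assert surf.heights.min() < -2.4  # bowl depth ~ R for a hemisphere
    assert surf.heights.max() == 0.0
    x = surf.x
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx - 5, yy - 5)
    rim_band = (r > 2.5) & (r < 2.6)
    assert np.all(surf.heights[rim_band] == 0.0)


def test_cap_footprint_clamped_with_warning():
    with pytest.warns(UserWarning):
        surf = build_spherical_cap_surface(1.5, "convex", 5.0, pitch=0.1)
    assert np.isclose(surf.heights.max(), 1.5, atol=5e-3)  # hemisphere of R=1.5
    with pytest.raises(ValueError):
        build_spherical_cap_surface(1.5, "convex", 5.0, pitch=0.1, clamp_footprint=False)


def test_wedge_slope_and_depth_range():
    surf = build_wedge_surface(45.0, max_depth=1.0, pitch=0.05, x0=2.0)
    # 45 deg: 1 cm lateral run -> 1 cm vertical drop
    h = surf.heights[100]
    x = surf.x
    i0, i1 = np.searchsorted(x, [2.2, 2.8])
    slope = (h[i1] - h[i0]) / (x[i1] - x[i0])
    assert np.isclose(slope, -1.0, atol=1e-6)
    assert surf.heights.min() == -1.0
    assert np.isclose(build_wedge_surface(0.0, pitch=0.1).heights.max(), 0.0)
    dm = depth_map(build_wedge_surface(30.0, pitch=0.1), 0.0)
    assert dm.delta_z.min() == 0.0 and np.isclose(dm.delta_z.max(), 1.0)


def test_wedge_normals_interior_cosine():
    surf = build_wedge_surface(60.0, max_depth=1.0, pitch=0.05, x0=2.0)
    nm = surface_normals(surf)
    x = surf.x
    cols = (x > 2.2) & (x < 2.35)  # interior of the incline
    assert np.allclose(nm.cos_theta[100, cols], 0.5, atol=1e-9)


def test_sphere_normals_match_analytic():
    surf = build_spherical_cap_surface(2.5, "convex", 5.0, pitch=0.05)
    nm = surface_normals(surf)
    x = surf.x
    ix = int(np.argmin(np.abs(x - (5.0 + 1.25))))  # pixel nearest 1.25 cm offset
    iy = int(np.argmin(np.abs(x - 5.0)))
    r = np.hypot(x[ix] - 5.0, x[iy] - 5.0)
    expected = np.sqrt(1 - (r / 2.5) ** 2)  # ~0.866 at the 1.25 cm offset
    assert np.isclose(nm.cos_theta[iy, ix], expected, atol=1e-3)


def test_normals_unit_length_everywhere():
    for surf in (
        build_wound_surface(0.1),
        build_spherical_cap_surface(3.0, "concave", 5.0, 0.1),
    ):
        nm = surface_normals(surf)
        norms = np.linalg.norm(nm.normals, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert np.all(nm.cos_theta > 0) and np.all(nm.cos_theta <= 1.0)


def test_wound_surface_structure():
    surf = build_wound_surface(0.05)
    x = surf.x
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx - 5, yy - 5)
    ring = (r > 1.2) & (r < 2.9)
    assert np.all(surf.heights[ring] > 0)  # convex annulus elevated
    crater = r < 1.0
    crest = surf.heights.max()
    assert np.all(surf.heights[crater] < crest)
    assert surf.heights[r < 0.2].max() < 0  # central depression below baseline
    outside = r > 3.1
    assert np.all(surf.heights[outside] == 0)
    # continuity: adjacent-pixel jumps bounded by pitch * tan(75 deg)
    jumps = np.maximum(
        np.abs(np.diff(surf.heights, axis=0)).max(),
        np.abs(np.diff(surf.heights, axis=1)).max(),
    )
    assert jumps < 0.05 * np.tan(np.radians(75))


def test_depth_map_concave_and_focus_plane():
    surf = build_spherical_cap_surface(2.5, "concave", 5.0, pitch=0.05)
    dm = depth_map(surf, focus_z=0.0)
    assert np.isclose(dm.delta_z.max(), 2.5, atol=2e-3)  # bowl center depth
    assert np.all(dm.delta_z >= 0)


def test_surface_extent_validation():
    with pytest.raises(ValueError):
        SurfaceField(np.zeros((50, 50)), pitch=0.1)  # 5 cm grid, 10 cm extent
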