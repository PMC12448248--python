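"""Correction models: algebra, clamping, masks, table interpolation."""

import numpy as np
import pytest

from curvedr.correction import (
    ANGLE_GRID,
    DEPTH_GRID,
    EmpiricalCorrectionTable,
    HeightCorrectionModel,
    apply_angle,
    apply_empirical,
    apply_height,
    apply_height_angle,
    apply_masked,
    convex_region_mask,
)
from curvedr.geometry import (
    DepthMap,
    NormalMap,
    build_flat_surface,
    build_wound_surface,
    depth_map,
    surface_normals,
)
from curvedr.transport import DRImage


def _img(values, wl=690, pitch=0.1):
    return DRImage(values=np.asarray(values, float), wavelength=wl, pitch=pitch)


def _height_model(coeffs=(0.05, 0.3, 1.0)):
    c = np.array(coeffs, dtype=float)  # (a, b, c), highest power first
    return HeightCorrectionModel(
        coeffs={690: c, 830: c},
        samples={690: np.zeros((2, 2)), 830: np.zeros((2, 2))},
        r2={690: 1.0, 830: 1.0},
    )


def test_height_identity_at_zero_depth():
    img = _img(np.full((100, 100), 2.0))
    dm = DepthMap(delta_z=np.zeros((100, 100)), focus_z=0.0)
    out = apply_height(img, dm, _height_model())
    assert np.array_equal(out.values, img.values)


def test_height_scalar_factor_and_clamp():
    model = _height_model((0.05, 0.3, 1.0))  # eps(1) = 1.35
    img = _img(np.ones((100, 100)))
    dm = DepthMap(delta_z=np.ones((100, 100)), focus_z=1.0)
    out = apply_height(img, dm, model)
    assert np.allclose(out.values, 1.35)
    # depths beyond the calibrated range are clamped to eps(3)
    dm_far = DepthMap(delta_z=np.full((100, 100), 7.0), focus_z=7.0)
    out_far = apply_height(img, dm_far, model)
    assert np.allclose(out_far.values, np.polyval(model.coeffs[690], 3.0))
    with pytest.raises(ValueError):
        apply_height(img, DepthMap(delta_z=-np.ones((100, 100)), focus_z=0), model)


def test_angle_division_and_mask():
    img = _img(np.ones((100, 100)))
    ct = np.full((100, 100), 0.5)
    ct[0, 0] = 0.1  # steeper than the 80 deg mask threshold
    nm = NormalMap(normals=np.zeros((100, 100, 3)), cos_theta=ct)
    out = apply_angle(img, nm, min_cos=0.17)
    assert np.isnan(out.values[0, 0])
    assert np.allclose(out.values[1:, 1:], 2.0)
    # cos(theta) = 1 leaves the image unchanged
    nm1 = NormalMap(normals=np.zeros((100, 100, 3)), cos_theta=np.ones((100, 100)))
    assert np.array_equal(apply_angle(img, nm1).values, img.values)


def test_model3_equals_composition_and_commutes():
    rng = np.random.default_rng(1)
    img = _img(rng.uniform(0.5, 2.0, (100, 100)))
    dz = rng.uniform(0, 2.5, (100, 100))
    ct = rng.uniform(0.3, 1.0, (100, 100))
    dm = DepthMap(delta_z=dz, focus_z=0.0)
    nm = NormalMap(normals=np.zeros((100, 100, 3)), cos_theta=ct)
    model = _height_model()
    combo = apply_height_angle(img, dm, nm, model)
    via_h_then_a = apply_angle(apply_height(img, dm, model), nm)
    via_a_then_h = apply_height(apply_angle(img, nm), dm, model)
    assert np.array_equal(combo.values, via_h_then_a.values)
    assert np.allclose(combo.values, via_a_then_h.values, rtol=1e-15)
    # spot check the arithmetic: eps(1)/0.5 on a unit pixel
    one = apply_height_angle(
        _img(np.ones((100, 100))),
        DepthMap(np.ones((100, 100)), 1.0),
        NormalMap(np.zeros((100, 100, 3)), np.full((100, 100), 0.5)),
        model,
    )
    assert np.allclose(one.values, 1.35 / 0.5)


def _toy_table():
    rho = np.outer(np.cos(np.radians(ANGLE_GRID)), 1.0 / (1.0 + 0.2 * DEPTH_GRID))
    return EmpiricalCorrectionTable(rho={690: rho, 830: rho})


def _bilinear_oracle(table, tg, dg, theta, dz):
    """Brute-force clamped bilinear interpolation."""
    t = min(max(theta, tg[0]), tg[-1])
    d = min(max(dz, dg[0]), dg[-1])
    i = min(np.searchsorted(tg, t, side="right") - 1, len(tg) - 2)
    j = min(np.searchsorted(dg, d, side="right") - 1, len(dg) - 2)
    ft = (t - tg[i]) / (tg[i + 1] - tg[i])
    fd = (d - dg[j]) / (dg[j + 1] - dg[j])
    return (
        table[i, j] * (1 - ft) * (1 - fd)
        + table[i + 1, j] * ft * (1 - fd)
        + table[i, j + 1] * (1 - ft) * fd
        + table[i + 1, j + 1] * ft * fd
    )


@pytest.mark.parametrize(
    "theta,dz",
    [(30.0, 0.5), (12.0, 0.34), (0.0, 0.0), (57.3, 0.91), (75.0, 1.8)],
)
def test_empirical_lookup_matches_bilinear_oracle(theta, dz):
    tbl = _toy_table()
    got = float(tbl.lookup(690, theta, dz))
    want = _bilinear_oracle(tbl.rho[690], tbl.theta_grid, tbl.dz_grid, theta, dz)
    assert np.isclose(got, want, atol=1e-12)


def test_empirical_grid_node_exact_and_flat_identity():
    tbl = _toy_table()
    assert np.isclose(float(tbl.lookup(690, 30.0, 0.5)), tbl.rho[690][6, 5], atol=1e-12)
    img = _img(np.ones((100, 100)))
    nm = NormalMap(np.zeros((100, 100, 3)), np.ones((100, 100)))
    dm = DepthMap(np.zeros((100, 100)), 0.0)
    out = apply_empirical(img, nm, dm, tbl)
    assert np.allclose(out.values, 1.0)  # rho(0, 0) = 1


def test_empirical_table_shape_validation():
    with pytest.raises(ValueError):
        EmpiricalCorrectionTable(rho={690: np.ones((5, 5))})


def test_corrections_preserve_positivity():
    rng = np.random.default_rng(2)
    img = _img(rng.uniform(0, 1, (100, 100)))
    tbl = _toy_table()
    nm = NormalMap(np.zeros((100, 100, 3)), rng.uniform(0.2, 1.0, (100, 100)))
    dm = DepthMap(rng.uniform(0, 1, (100, 100)), 0.0)
    for out in (
        apply_height(img, dm, _height_model()),
        apply_angle(img, nm),
        apply_empirical(img, nm, dm, tbl),
    ):
        vals = out.values[np.isfinite(out.values)]
        assert np.all(vals >= 0)


def test_convex_region_mask_wound_and_flat():
    wound = build_wound_surface(0.1)
    mask = convex_region_mask(wound)
    c = wound.shape[0] // 2
    assert not mask[c, c]  # central depression excluded
    x = wound.x
    ring_ix = np.searchsorted(x, 5.0 + 2.05)
    assert mask[c, ring_ix]  # bulge annulus included
    assert not convex_region_mask(build_flat_surface(0.1)).any()
    # masked application: raw values outside, corrected inside
    img = _img(np.ones(wound.shape))
    corrected = _img(np.full(wound.shape, 3.0))
    out = apply_masked(img, corrected, mask)
    assert out.values[c, c] == 1.0
    assert out.values[c, ring_ix] == 3.0


def test_every_correction_is_identity_on_flat_at_focus(surrogate_cal):
    """On a flat surface at the focal plane all four models are identities
    (up to the Monte-Carlo-free surrogate's rho(0,0) calibration ratio)."""
    height, table = surrogate_cal
    surf = build_flat_surface(0.1)
    img = _img(np.full(surf.shape, 0.7))
    dm = depth_map(surf, 0.0)
    nm = surface_normals(surf)
    assert np.allclose(apply_height(img, dm, height).values, 0.7)
    assert np.allclose(apply_angle(img, nm).values, 0.7)
    assert np.allclose(apply_height_angle(img, dm, nm, height).values, 0.7)
    out4 = apply_empirical(img, nm, dm, table)
    assert np.allclose(out4.values, 0.7, rtol=1e-6)
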