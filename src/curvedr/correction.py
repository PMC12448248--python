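"""Curvature correction of diffuse-reflectance images.

Four models restore the DR signal of a curved surface toward what a flat
surface at the focused imaging plane would have produced:

1. height:        corrected = raw * eps(dz),   eps = baseline / displaced >= 1
2. angle:         corrected = raw / cos(theta)            (Lambertian)
3. height+angle:  corrected = raw * eps(dz) / cos(theta)
4. empirical:     corrected = raw / rho(theta, dz),  rho = inclined / flat <= 1

eps(dz) is calibrated by rigidly translating the flat phantom away from the
camera (a quadratic in dz); rho(theta, dz) is tabulated from inclined-plane
(wedge) phantoms on a 13 x 11 angle x depth grid and interpolated bilinearly.
Out-of-range depths/angles are clamped to the calibrated range, never
extrapolated, and clamp counts are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import (
    DepthMap,
    NormalMap,
    SurfaceField,
    TissueModel,
    build_wedge_surface,
    wedge_depth_profile,
)
from .transport import CollectorSpec, DRImage, SourceSpec, collect_image, run_transport

log = logging.getLogger(__name__)

DZ_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)  # 31 planes
ANGLE_GRID = np.arange(0.0, 60.0 + 1e-9, 5.0)  # 13 angles, deg
DEPTH_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)  # 11 depths, cm
MIN_COS_DEFAULT = 0.17  # mask pixels steeper than ~80 deg


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class HeightCorrectionModel:
    """Quadratic height-loss factor eps(dz) = a dz^2 + b dz + c per wavelength."""

    coeffs: dict[int, np.ndarray]  # wavelength -> (a, b, c)
    samples: dict[int, np.ndarray]  # wavelength -> (n, 2) array of (dz, eps)
    r2: dict[int, float]
    dz_range: tuple[float, float] = (0.0, 3.0)

    def epsilon(self, wavelength: int, dz) -> np.ndarray:
        """Evaluate eps at (clamped) displacement dz."""
        c = self.coeffs[int(wavelength)]
        dzc = np.clip(dz, *self.dz_range)
        return np.polyval(c, dzc)

    def clamp_count(self, dz) -> int:
        d = np.asarray(dz)
        return int(np.sum((d < self.dz_range[0]) | (d > self.dz_range[1])))


@dataclass
class EmpiricalCorrectionTable:
    """rho(theta, dz) joint height/angle factor on the calibration grid."""

    rho: dict[int, np.ndarray]  # wavelength -> (n_theta, n_dz)
    theta_grid: np.ndarray = field(default_factory=lambda: ANGLE_GRID.copy())
    dz_grid: np.ndarray = field(default_factory=lambda: DEPTH_GRID.copy())
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        for wl, tbl in self.rho.items():
            if tbl.shape != (self.theta_grid.size, self.dz_grid.size):
                raise ValueError(f"table shape mismatch at {wl} nm")

    def lookup(self, wavelength: int, theta_deg, dz) -> np.ndarray:
        """Bilinear interpolation, clamped to the calibrated grid."""
        tbl = self.rho[int(wavelength)]
        interp = RegularGridInterpolator(
            (self.theta_grid, self.dz_grid), tbl, method="linear"
        )
        t = np.clip(theta_deg, self.theta_grid[0], self.theta_grid[-1])
        d = np.clip(dz, self.dz_grid[0], self.dz_grid[-1])
        pts = np.stack([np.ravel(t), np.ravel(d)], axis=-1)
        return interp(pts).reshape(np.shape(t))

    def clamp_count(self, theta_deg, dz) -> int:
        t = np.asarray(theta_deg)
        d = np.asarray(dz)
        return int(
            np.sum(
                (t < self.theta_grid[0])
                | (t > self.theta_grid[-1])
                | (d < self.dz_grid[0])
                | (d > self.dz_grid[-1])
            )
        )


# ---------------------------------------------------------------------------
# calibration (image-level cores; MC drivers below)
# ---------------------------------------------------------------------------

def _interior_mask(shape: tuple[int, int], pitch: float, margin: float) -> np.ndarray:
    ny, nx = shape
    k = int(round(margin / pitch))
    m = np.zeros(shape, dtype=bool)
    m[k : ny - k, k : nx - k] = True
    return m


def fit_height_model_from_images(
    images_by_dz: dict[int, Sequence[DRImage]],
    dz_grid: np.ndarray = DZ_GRID,
    interior_margin: float = 1.0,
) -> HeightCorrectionModel:
    """Fit eps(dz) from a sweep of flat-phantom images at each displacement.

    eps_n is the ratio of the mean baseline signal to the mean signal at dz_n
    over the illuminated interior.
    """
    coeffs: dict[int, np.ndarray] = {}
    samples: dict[int, np.ndarray] = {}
    r2: dict[int, float] = {}
    for wl, images in images_by_dz.items():
        if len(images) != len(dz_grid):
            raise ValueError("one image per displacement is required")
        mask = _interior_mask(images[0].shape, images[0].pitch, interior_margin)
        means = np.array([float(img.values[mask].mean()) for img in images])
        if np.any(means <= 0):
            raise ValueError("non-positive mean DR signal in the calibration sweep")
        eps = means[0] / means
        c = np.polyfit(dz_grid, eps, 2)
        resid = eps - np.polyval(c, dz_grid)
        ss_tot = float(np.sum((eps - eps.mean()) ** 2))
        r2[wl] = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        coeffs[wl] = c
        samples[wl] = np.column_stack([dz_grid, eps])
    return HeightCorrectionModel(
        coeffs=coeffs,
        samples=samples,
        r2=r2,
        dz_range=(float(dz_grid[0]), float(dz_grid[-1])),
    )


def calibrate_height_model(
    flat_model: TissueModel,
    source: SourceSpec,
    collector: CollectorSpec,
    dz_grid: np.ndarray = DZ_GRID,
    n_photons: int = 200_000,
    seed: int = 1,
    wavelengths: Sequence[int] = (690, 830),
    interior_margin: float = 1.0,
) -> HeightCorrectionModel:
    """Simulate the displacement sweep and fit the quadratic height factor.

    Under the uniform collimated calibration source, translating the phantom
    rigidly translates every escape event, so a single transport run per
    wavelength is re-collected at each displacement (exact, and it removes
    almost all Monte-Carlo scatter from the eps ratios).
    """
    if np.any(flat_model.surface.heights != 0.0):
        raise ValueError("height calibration requires the flat phantom")
    images_by_dz: dict[int, list[DRImage]] = {}
    for k, wl in enumerate(wavelengths):
        src = SourceSpec(
            kind="uniform",
            wavelength=wl,
            center=source.center,
            spatial_width=source.spatial_width,
            angular_width_deg=source.angular_width_deg,
            standoff=source.standoff,
        )
        events, _ = run_transport(
            flat_model, src, n_photons, seed + 7919 * k, focus_z=collector.focus_z
        )
        images_by_dz[wl] = [
            collect_image(events.translated(-dz), collector, n_photons, wl)
            for dz in dz_grid
        ]
    return fit_height_model_from_images(images_by_dz, dz_grid, interior_margin)


def fit_empirical_table_from_images(
    flat_image: DRImage,
    wedge_images: dict[float, DRImage],
    wedge_depths: dict[float, np.ndarray],
    angle_grid: np.ndarray = ANGLE_GRID,
    dz_grid: np.ndarray = DEPTH_GRID,
    interior_margin: float = 1.0,
    height_model: Optional[HeightCorrectionModel] = None,
    smooth: bool = True,
) -> np.ndarray:
    """Tabulate rho(theta, dz) from wedge/flat image ratios at one wavelength.

    When a height model is supplied (the standard workflow), each wedge
    contributes a single angular factor A(theta) -- the flat-signal-weighted
    ratio of inclined to height-compensated flat signal over all incline
    columns -- and the table row is A(theta)/eps(dz).  This separable
    estimator uses every photon on the incline to constrain one number, so
    the table stays smooth at desk-scale photon counts; the depth dependence
    comes from the height calibration, which measures it far more precisely
    than thin per-depth bins on a wedge could.  Without a height model, each
    row is a flat-signal-weighted quadratic fit of the per-column ratios
    against the analytic column depth (which also fills depth bins the wedge
    cannot reach inside the field).  The theta = 0 column is the pure height
    factor anchored at the measured rho(0, 0).
    """
    ny, nx = flat_image.shape
    pitch = flat_image.pitch
    k = int(round(interior_margin / pitch))
    rows = slice(k, ny - k)
    table = np.full((angle_grid.size, dz_grid.size), np.nan)
    max_depth = float(dz_grid[-1])

    if height_model is not None:
        num, den = angular_factor_sums(
            flat_image, wedge_images, wedge_depths, angle_grid, dz_grid,
            interior_margin, height_model,
        )
        wl = flat_image.wavelength
        angular = _pava_decreasing(num / den)
        return np.clip(
            np.outer(angular, 1.0 / np.asarray(height_model.epsilon(wl, dz_grid))),
            1e-6,
            1.2,
        )

    for i, theta in enumerate(angle_grid):
        if theta == 0.0:
            continue
        img = wedge_images[float(theta)]
        depth_cols = wedge_depths[float(theta)]  # per-column analytic depth
        # skip columns within ~2 pixels of the incline's creases, where the
        # finite-difference surface normal (hence the tilt factor) is smeared
        buffer = 2.0 * pitch * np.tan(np.radians(theta))
        on = (depth_cols > buffer) & (depth_cols < max_depth - buffer)
        on[:k] = False
        on[nx - k :] = False
        cols = np.where(on)[0]
        if cols.size < 3:
            raise ValueError(f"too few incline columns at theta={theta}")
        fsum = flat_image.values[rows][:, cols].sum(axis=0)
        wsum = img.values[rows][:, cols].sum(axis=0)
        ok = fsum > 0
        if ok.sum() < 3:
            raise ValueError(f"no flat signal on the incline at theta={theta}")
        ratios = wsum[ok] / fsum[ok]
        depths = depth_cols[cols][ok]
        if smooth or depths.max() < max_depth - 1e-9:
            deg = 2 if np.unique(depths).size > 2 else 1
            c = np.polyfit(depths, ratios, deg, w=np.sqrt(fsum[ok]))
            table[i] = np.polyval(c, dz_grid)
            gap = dz_grid[1] - dz_grid[0]
            if depths.max() < max_depth - gap:
                log.warning(
                    "theta=%s: incline reaches only %.2f cm; deeper cells "
                    "extrapolated from the depth fit",
                    theta,
                    depths.max(),
                )
        else:
            # nearest-measurement fallback (no smoothing requested)
            idx = np.abs(depths[None, :] - dz_grid[:, None]).argmin(axis=1)
            table[i] = ratios[idx]

    # theta = 0: the wedge degenerates to the flat phantom, so only the
    # zero-depth cell is measurable; scale the nearest angle's depth profile.
    img0 = wedge_images[0.0]
    sel0 = _interior_mask((ny, nx), pitch, interior_margin)
    rho00 = float(img0.values[sel0].sum() / flat_image.values[sel0].sum())
    ref = table[1] / table[1, 0]
    table[0] = rho00 * ref
    log.warning("no height model supplied; theta=0 column scaled from 5 deg")
    table[0, 0] = rho00
    return np.clip(table, 1e-6, 1.2)


def angular_factor_sums(
    flat_image: DRImage,
    wedge_images: dict[float, DRImage],
    wedge_depths: dict[float, np.ndarray],
    angle_grid: np.ndarray,
    dz_grid: np.ndarray,
    interior_margin: float,
    height_model: HeightCorrectionModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle numerator/denominator sums of the angular factor A(theta).

    A(theta) = sum(wedge signal) / sum(flat signal / eps(depth)) over
    mid-incline columns: within ~0.3 cm (in depth) of the top crease lateral
    diffusion from the bright flat top contaminates the ratio, and the bottom
    crease is excluded symmetrically.  Keeping the sums separate lets callers
    pool them across wavelengths before taking the ratio.
    """
    ny, nx = flat_image.shape
    pitch = flat_image.pitch
    wl = flat_image.wavelength
    k = int(round(interior_margin / pitch))
    rows = slice(k, ny - k)
    max_depth = float(dz_grid[-1])
    num = np.zeros(angle_grid.size)
    den = np.zeros(angle_grid.size)
    for i, theta in enumerate(angle_grid):
        img = wedge_images[float(theta)]
        if theta == 0.0:
            sel0 = _interior_mask((ny, nx), pitch, interior_margin)
            num[i] = float(img.values[sel0].sum())
            den[i] = float(flat_image.values[sel0].sum())
            continue
        depth_cols = wedge_depths[float(theta)]
        buffer = 2.0 * pitch * np.tan(np.radians(theta))
        on = (depth_cols > buffer) & (depth_cols < max_depth - buffer)
        on[:k] = False
        on[nx - k :] = False
        cols = np.where(on)[0]
        if cols.size < 3:
            raise ValueError(f"too few incline columns at theta={theta}")
        fsum = flat_image.values[rows][:, cols].sum(axis=0)
        wsum = img.values[rows][:, cols].sum(axis=0)
        ok = fsum > 0
        if ok.sum() < 2:
            raise ValueError(f"no flat signal on the incline at theta={theta}")
        depths = depth_cols[cols][ok]
        window = (depths >= min(0.3, 0.6 * depths.max())) & (
            depths <= 0.9 * max_depth
        )
        if window.sum() < 2:
            window = np.ones_like(depths, dtype=bool)
        eps_cols = np.asarray(height_model.epsilon(wl, depths[window]))
        num[i] = float(wsum[ok][window].sum())
        den[i] = float((fsum[ok][window] / eps_cols).sum())
    return num, den


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-increasing sequence (unit weights)."""
    vals = list(y.astype(float))
    wts = [1.0] * len(vals)
    blocks = []  # (value, weight)
    for v, w in zip(vals, wts):
        blocks.append([v, w])
        while len(blocks) > 1 and blocks[-2][0] < blocks[-1][0]:
            v2, w2 = blocks.pop()
            v1, w1 = blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
    out = []
    for v, w in blocks:
        out.extend([v] * int(round(w)))
    return np.array(out)


def calibrate_empirical(
    flat_model: TissueModel,
    wedge_builder: Callable[[float], SurfaceField],
    source: SourceSpec,
    collector: CollectorSpec,
    angle_grid: np.ndarray = ANGLE_GRID,
    dz_grid: np.ndarray = DEPTH_GRID,
    n_photons: int = 200_000,
    seed: int = 1,
    wavelengths: Sequence[int] = (690, 830),
    height_model: Optional[HeightCorrectionModel] = None,
    layers: Optional[list] = None,
    x0: float = 2.0,
) -> EmpiricalCorrectionTable:
    """Simulate the wedge sweep and tabulate rho(theta, dz) per wavelength.

    Wedge surfaces (and their images) may use a finer pitch than the study
    images so that steep inclines still span enough image columns for the
    per-wedge depth regression; the collector pitch follows the builder's.

    With a height model (the standard workflow) the *shape* of the angular
    factor A(theta) is estimated from the wedge simulations of all requested
    wavelengths pooled together -- the escape lobe that sets it is fixed by
    the refractive indices, which are identical at 690 and 830 nm in this
    tissue model -- while each wavelength rescales the pooled dimming
    amplitude by a single factor d_wl = (1 - r_wl) / (1 - r_pooled), with
    r_wl that wavelength's aggregate inclined-to-flat ratio over every wedge
    (A_wl(theta) = 1 - d_wl * (1 - A(theta))).  One amplitude parameter per
    wavelength is measurable to well under a percent at desk-scale counts,
    so the wavelength-differential curvature response (an albedo effect) is
    preserved without the per-wedge cross-wavelength noise that the MBLL
    inversion would otherwise amplify into the hemoglobin maps.  The depth
    factor is per-wavelength from the height calibration throughout.
    """
    import dataclasses

    from .geometry import build_layered_model

    wedge_pitch = wedge_builder(0.0).pitch
    collector = dataclasses.replace(collector, pitch=wedge_pitch)
    layer_specs = layers if layers is not None else flat_model.layers
    rho: dict[int, np.ndarray] = {}
    num_pool = np.zeros(np.asarray(angle_grid).size)
    den_pool = np.zeros(np.asarray(angle_grid).size)
    sums_by_wl: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k, wl in enumerate(wavelengths):
        src = SourceSpec(
            kind="uniform",
            wavelength=wl,
            center=source.center,
            spatial_width=source.spatial_width,
            angular_width_deg=source.angular_width_deg,
            standoff=source.standoff,
        )
        flat_ev, _ = run_transport(
            flat_model, src, n_photons, seed + 7919 * k, focus_z=collector.focus_z
        )
        flat_img = collect_image(flat_ev, collector, n_photons, wl)
        wedge_images: dict[float, DRImage] = {}
        wedge_depths: dict[float, np.ndarray] = {}
        for j, theta in enumerate(angle_grid):
            if theta == 0.0:
                surf = wedge_builder(0.0)
            else:
                surf = wedge_builder(float(theta))
            model = build_layered_model(surf, layer_specs)
            ev, _ = run_transport(
                model,
                src,
                n_photons,
                seed + 7919 * k + 131 * (j + 1),
                focus_z=collector.focus_z,
            )
            wedge_images[float(theta)] = collect_image(ev, collector, n_photons, wl)
            wedge_depths[float(theta)] = wedge_depth_profile(
                float(theta), float(dz_grid[-1]), surf.pitch, x0
            )
        if height_model is not None:
            num, den = angular_factor_sums(
                flat_img, wedge_images, wedge_depths,
                np.asarray(angle_grid, float), np.asarray(dz_grid, float),
                1.0, height_model,
            )
            num_pool += num
            den_pool += den
            sums_by_wl[int(wl)] = (num, den)
        else:
            rho[wl] = fit_empirical_table_from_images(
                flat_img,
                wedge_images,
                wedge_depths,
                angle_grid,
                dz_grid,
                height_model=None,
            )
    if height_model is not None:
        angular = _pava_decreasing(num_pool / den_pool)
        r_pool = num_pool[1:].sum() / den_pool[1:].sum()
        for wl in wavelengths:
            num, den = sums_by_wl[int(wl)]
            r_wl = num[1:].sum() / den[1:].sum()
            d_wl = (1.0 - r_wl) / (1.0 - r_pool) if abs(1.0 - r_pool) > 1e-9 else 1.0
            a_wl = 1.0 - d_wl * (1.0 - angular)
            eps = np.asarray(height_model.epsilon(wl, np.asarray(dz_grid, float)))
            rho[int(wl)] = np.clip(np.outer(a_wl, 1.0 / eps), 1e-6, 1.2)
    return EmpiricalCorrectionTable(
        rho=rho,
        theta_grid=np.asarray(angle_grid, float),
        dz_grid=np.asarray(dz_grid, float),
    )


def default_wedge_builder(pitch: float = 0.05, max_depth: float = 1.0, x0: float = 2.0):
    """Wedge factory used by the empirical calibration workflow."""

    def build(theta: float) -> SurfaceField:
        return build_wedge_surface(theta, max_depth=max_depth, pitch=pitch, x0=x0)

    return build


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def _clone(image: DRImage, values: np.ndarray, note: str) -> DRImage:
    meta = dict(image.meta)
    meta.setdefault("corrections", []);  meta["corrections"] = meta["corrections"] + [note]
    return DRImage(values=values, wavelength=image.wavelength, pitch=image.pitch, meta=meta)


def apply_height(
    image: DRImage, depth: DepthMap, model: HeightCorrectionModel
) -> DRImage:
    """Model 1: multiply each pixel by eps(dz)."""
    dz = depth.delta_z
    if np.any(dz < 0):
        raise ValueError("negative depth in depth map")
    if dz.shape != image.shape:
        raise ValueError("depth map grid does not match the image")
    n_clamped = model.clamp_count(dz)
    if n_clamped:
        log.info("apply_height: %d pixels clamped to the calibrated range", n_clamped)
    eps = model.epsilon(image.wavelength, dz)
    return _clone(image, image.values * eps, "height")


def apply_angle(
    image: DRImage, normals: NormalMap, min_cos: float = MIN_COS_DEFAULT
) -> DRImage:
    """Model 2: divide each pixel by cos(theta); mask extreme inclinations."""
    ct = normals.cos_theta
    if ct.shape != image.shape:
        raise ValueError("normal map grid does not match the image")
    out = np.where(ct >= min_cos, image.values / np.maximum(ct, min_cos), np.nan)
    n_masked = int(np.sum(ct < min_cos))
    if n_masked:
        log.info("apply_angle: %d pixels masked (cos theta < %.3f)", n_masked, min_cos)
    return _clone(image, out, "angle")


def apply_height_angle(
    image: DRImage,
    depth: DepthMap,
    normals: NormalMap,
    height_model: HeightCorrectionModel,
    min_cos: float = MIN_COS_DEFAULT,
) -> DRImage:
    """Model 3: height and angle corrections composed (order-independent)."""
    return apply_angle(apply_height(image, depth, height_model), normals, min_cos)


def apply_empirical(
    image: DRImage,
    normals: NormalMap,
    depth: DepthMap,
    table: EmpiricalCorrectionTable,
) -> DRImage:
    """Model 4: divide each pixel by the interpolated rho(theta, dz)."""
    if normals.cos_theta.shape != image.shape or depth.delta_z.shape != image.shape:
        raise ValueError("grids do not match the image")
    theta = np.degrees(np.arccos(np.clip(normals.cos_theta, -1.0, 1.0)))
    n_clamped = table.clamp_count(theta, depth.delta_z)
    if n_clamped:
        log.info("apply_empirical: %d pixels clamped to the table range", n_clamped)
    rho = table.lookup(image.wavelength, theta, depth.delta_z)
    return _clone(image, image.values / rho, "empirical")


def convex_region_mask(surface: SurfaceField) -> np.ndarray:
    """Pixels on elevated (convex) structure: h > 0.

    The wound workflow applies corrections only where this mask is true;
    depressed (concave) regions are left uncorrected.
    """
    return surface.heights > 0.0


def apply_masked(image: DRImage, corrected: DRImage, mask: np.ndarray) -> DRImage:
    """Corrected values inside the mask, raw values elsewhere."""
    vals = np.where(mask, corrected.values, image.values)
    return _clone(image, vals, "masked")
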