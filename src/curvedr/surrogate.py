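"""Deterministic analytic DR surrogate for millisecond-scale testing.

The surrogate replaces the Monte-Carlo engine with the exactly separable
distortion the correction models assume:

    I(x, y) = S(x, y) * cos(theta(x, y)) * f(|h(x, y)|)

with S a base illumination profile, cos(theta) the surface tilt factor and f
a monotone height-loss function with f(0) = 1.  Calibrations run on surrogate
images therefore have exact closed-form targets (eps = 1/f, rho = cos * f),
which makes every correction and error-analysis code path testable without
photon noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .correction import (
    ANGLE_GRID,
    DEPTH_GRID,
    DZ_GRID,
    EmpiricalCorrectionTable,
    HeightCorrectionModel,
    fit_empirical_table_from_images,
    fit_height_model_from_images,
)
from .geometry import (
    SurfaceField,
    build_flat_surface,
    build_wedge_surface,
    surface_normals,
    wedge_depth_profile,
)
from .transport import DRImage


def default_height_loss(dz):
    """Quadratic-reciprocal height loss, mimicking a quadratic eps(dz)."""
    return 1.0 / (1.0 + 0.3 * np.asarray(dz) + 0.05 * np.asarray(dz) ** 2)


@dataclass
class SurrogateSpec:
    """Base signal, height-loss function and optional multiplicative noise."""

    base: str = "uniform"  # "uniform" | "gaussian"
    amplitude: float = 1.0e-6
    beam_center: tuple[float, float] = (5.0, 5.0)
    beam_radius: float = 3.0  # 1/e^2 radius for the gaussian base, cm
    height_loss: Callable = field(default_factory=lambda: default_height_loss)
    noise_scale: float = 0.0
    seed: int = 0

    def base_signal(self, surface: SurfaceField) -> np.ndarray:
        if self.base == "uniform":
            return np.full(surface.shape, self.amplitude)
        xx, yy = np.meshgrid(surface.x, surface.y)
        r2 = (xx - self.beam_center[0]) ** 2 + (yy - self.beam_center[1]) ** 2
        return self.amplitude * np.exp(-2.0 * r2 / self.beam_radius**2)


def surrogate_dr(
    surface: SurfaceField, spec: SurrogateSpec, wavelength: int = 690
) -> DRImage:
    """Analytic DR image I = S * cos(theta) * f(|h|)."""
    s = spec.base_signal(surface)
    ct = surface_normals(surface).cos_theta
    f = spec.height_loss(np.abs(surface.heights))
    values = s * ct * f
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * (1.0 + spec.noise_scale * rng.standard_normal(values.shape))
    return DRImage(
        values=values,
        wavelength=wavelength,
        pitch=surface.pitch,
        meta={"surrogate": True},
    )


def surrogate_calibration(
    spec: Optional[SurrogateSpec] = None,
    pitch: float = 0.05,
    wavelengths: Sequence[int] = (690,),
    dz_grid: np.ndarray = DZ_GRID,
    angle_grid: np.ndarray = ANGLE_GRID,
    depth_grid: np.ndarray = DEPTH_GRID,
    wedge_x0: float = 2.0,
) -> tuple[HeightCorrectionModel, EmpiricalCorrectionTable]:
    """Run the real calibration code paths on surrogate images.

    The recovered eps(dz) equals 1/f(dz) and rho(theta, dz) equals
    cos(theta) * f(dz) up to fit/interpolation error.
    """
    spec = spec or SurrogateSpec()
    flat = build_flat_surface(pitch)

    # height sweep: flat surface translated down by dz
    images_by_dz: dict[int, list[DRImage]] = {}
    for wl in wavelengths:
        sweep = []
        for dz in dz_grid:
            shifted = SurfaceField(flat.heights - dz, pitch)
            sweep.append(surrogate_dr(shifted, spec, wl))
        images_by_dz[wl] = sweep
    height_model = fit_height_model_from_images(images_by_dz, dz_grid)

    flat_img = {wl: surrogate_dr(flat, spec, wl) for wl in wavelengths}
    rho: dict[int, np.ndarray] = {}
    for wl in wavelengths:
        wedge_images = {}
        wedge_depths = {}
        for theta in angle_grid:
            surf = build_wedge_surface(
                float(theta), max_depth=float(depth_grid[-1]), pitch=pitch, x0=wedge_x0
            )
            wedge_images[float(theta)] = surrogate_dr(surf, spec, wl)
            wedge_depths[float(theta)] = wedge_depth_profile(
                float(theta), float(depth_grid[-1]), pitch, wedge_x0
            )
        rho[wl] = fit_empirical_table_from_images(
            flat_img[wl],
            wedge_images,
            wedge_depths,
            angle_grid,
            depth_grid,
            height_model=height_model,
        )
    table = EmpiricalCorrectionTable(
        rho=rho, theta_grid=np.asarray(angle_grid, float), dz_grid=np.asarray(depth_grid, float)
    )
    return height_model, table
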