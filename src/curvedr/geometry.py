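"""Layered phantom geometry: curved top surfaces, normals, depth maps.

Coordinates are right-handed with z pointing up toward the camera.  The
baseline plane z = 0 coincides with the flat portion of every phantom's top
surface; heights h(x, y) are stored relative to it (positive = elevated
toward the camera, negative = depressed).  Pixel (0, 0) sits at the field
corner and pixel centers lie at half-pitch offsets.

Layers are vertical offsets of the top surface: the thickness of each layer
is measured along z, not along the local normal.  This is an approximation
for strongly sloped surfaces but matches the way the curved phantoms are
constructed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import AMBIENT, LayerSpec, OpticalProperties

DOMAIN_XY = 10.0  # cm, lateral extent of the phantom top surface
DOMAIN_Z = 6.0  # cm, depth of the simulation domain
DEFAULT_PITCH = 0.05  # cm


def _axis(pitch: float, extent: float = DOMAIN_XY) -> np.ndarray:
    n = int(round(extent / pitch))
    if abs(n * pitch - extent) > 1e-9:
        raise ValueError(f"pitch {pitch} does not divide the {extent} cm extent evenly")
    return (np.arange(n) + 0.5) * pitch


@dataclass
class SurfaceField:
    """Top-surface height field h(x, y) on a regular pixel grid."""

    heights: np.ndarray  # (ny, nx) cm, indexed [iy, ix]
    pitch: float
    extent: tuple[float, float] = (DOMAIN_XY, DOMAIN_XY)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        ny, nx = self.heights.shape
        if abs(nx * self.pitch - self.extent[0]) > 1e-6 or abs(
            ny * self.pitch - self.extent[1]
        ) > 1e-6:
            raise ValueError("height grid does not cover the stated extent")
        if np.max(np.abs(self.heights)) > DOMAIN_Z:
            raise ValueError("|h| exceeds the domain depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def x(self) -> np.ndarray:
        return _axis(self.pitch, self.extent[0])

    @property
    def y(self) -> np.ndarray:
        return _axis(self.pitch, self.extent[1])

    def height_at(self, x, y):
        """Bilinear height lookup at arbitrary lateral positions (cm)."""
        return _bilinear(self.heights, np.asarray(x), np.asarray(y), self.pitch)


def _bilinear(grid: np.ndarray, x, y, pitch: float):
    ny, nx = grid.shape
    fx = np.clip(x / pitch - 0.5, 0.0, nx - 1.000001)
    fy = np.clip(y / pitch - 0.5, 0.0, ny - 1.000001)
    ix = np.floor(fx).astype(np.int64)
    iy = np.floor(fy).astype(np.int64)
    ix1 = np.minimum(ix + 1, nx - 1)
    iy1 = np.minimum(iy + 1, ny - 1)
    tx = fx - ix
    ty = fy - iy
    return (
        grid[iy, ix] * (1 - tx) * (1 - ty)
        + grid[iy, ix1] * tx * (1 - ty)
        + grid[iy1, ix] * (1 - tx) * ty
        + grid[iy1, ix1] * tx * ty
    )


@dataclass
class NormalMap:
    """Per-pixel outward unit surface normals and cos(theta) to vertical."""

    normals: np.ndarray  # (ny, nx, 3)
    cos_theta: np.ndarray  # (ny, nx), n_hat . z_hat


@dataclass
class DepthMap:
    """Per-pixel vertical distance below the focused imaging plane (cm)."""

    delta_z: np.ndarray  # (ny, nx), >= 0
    focus_z: float


@dataclass
class TissueModel:
    """Layered phantom: curved top surface over an ordered layer stack."""

    surface: SurfaceField
    layers: list[LayerSpec]
    ambient: OpticalProperties = field(default_factory=lambda: AMBIENT)

    def __post_init__(self) -> None:
        if sum(l.thickness for l in self.layers) > DOMAIN_Z + 1e-9:
            raise ValueError("layer thickness sum exceeds the domain depth")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative depth-below-surface of each layer's lower boundary."""
        return np.cumsum([l.thickness for l in self.layers])

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def properties(self, wavelength: int) -> list[OpticalProperties]:
        return [l.at(wavelength) for l in self.layers]


def build_layered_model(
    surface: SurfaceField, layer_specs: list[LayerSpec]
) -> TissueModel:
    """Assemble a tissue model and validate wavelength coverage."""
    if not layer_specs:
        raise ValueError("at least one layer is required")
    for layer in layer_specs:
        for wl in (690, 830):
            if wl not in layer.props:
                raise ValueError(
                    f"layer {layer.name!r} is missing {wl} nm optical properties"
                )
    return TissueModel(surface=surface, layers=list(layer_specs))


def medium_at(model: TissueModel, position) -> str:
    """Medium label at a 3-D point (cm): ambient or a layer name.

    Layer intervals in depth-below-surface are closed below, open above, so a
    point exactly on the surface belongs to the first layer.
    """
    x, y, z = (float(c) for c in position)
    ex, ey = model.surface.extent
    if not (0.0 <= x <= ex and 0.0 <= y <= ey):
        raise ValueError("position outside the lateral domain")
    if not (-DOMAIN_Z <= z <= DOMAIN_Z):
        raise ValueError("position outside the vertical domain")
    h = float(model.surface.height_at(x, y))
    depth = h - z
    if depth < 0:
        return "ambient"
    prev = 0.0
    for layer, bound in zip(model.layers, model.boundaries):
        if prev <= depth < bound:
            return layer.name
        prev = bound
    return "ambient"  # below the tissue stack


# ---------------------------------------------------------------------------
# surface builders
# ---------------------------------------------------------------------------

def build_flat_surface(pitch: float = DEFAULT_PITCH) -> SurfaceField:
    """Flat phantom top surface, h = 0 everywhere."""
    n = int(round(DOMAIN_XY / pitch))
    return SurfaceField(np.zeros((n, n)), pitch)


def build_spherical_cap_surface(
    radius: float,
    polarity: str,
    footprint_diameter: float = 5.0,
    pitch: float = DEFAULT_PITCH,
    clamp_footprint: bool = True,
) -> SurfaceField:
    """Spherical cap (convex bump or concave bowl) centered in the field.

    The cap meets the surrounding plane continuously: h = 0 at the rim of the
    footprint.  For radii smaller than half the footprint the footprint is
    clamped to the sphere diameter (with a warning) unless clamping is
    disabled, in which case an error is raised.
    """
    if polarity not in ("convex", "concave"):
        raise ValueError("polarity must be 'convex' or 'concave'")
    if radius < 1.5:
        raise ValueError("radius of curvature must be >= 1.5 cm")
    if footprint_diameter > 2 * radius:
        if not clamp_footprint:
            raise ValueError("footprint exceeds the sphere diameter")
        warnings.warn(
            f"footprint {footprint_diameter} cm exceeds 2R={2 * radius} cm; clamping",
            stacklevel=2,
        )
        footprint_diameter = 2 * radius
    x = _axis(pitch)
    xx, yy = np.meshgrid(x, x)
    c = DOMAIN_XY / 2.0
    r = np.hypot(xx - c, yy - c)
    r_max = footprint_diameter / 2.0
    h = np.zeros_like(r)
    inside = r < r_max
    rim = np.sqrt(max(radius**2 - r_max**2, 0.0))
    h[inside] = np.sqrt(radius**2 - r[inside] ** 2) - rim
    if polarity == "concave":
        h = -h
    return SurfaceField(h, pitch)


def build_wedge_surface(
    angle_deg: float,
    max_depth: float = 1.0,
    pitch: float = DEFAULT_PITCH,
    x0: float = 2.0,
) -> SurfaceField:
    """Inclined-plane (rhombus) phantom used for the empirical calibration.

    Flat at z = 0 for x < x0, then descending at the stated angle until
    max_depth is reached, then flat at -max_depth.
    """
    if not 0.0 <= angle_deg < 90.0:
        raise ValueError("wedge angle must lie in [0, 90) degrees")
    x = _axis(pitch)
    slope = np.tan(np.radians(angle_deg))
    h_line = -np.clip((x - x0) * slope, 0.0, max_depth)
    h = np.broadcast_to(h_line, (x.size, x.size)).copy()
    return SurfaceField(h, pitch)


def wedge_depth_profile(
    angle_deg: float, max_depth: float = 1.0, pitch: float = DEFAULT_PITCH, x0: float = 2.0
) -> np.ndarray:
    """Analytic per-column depth of the wedge below its top plane (cm)."""
    x = _axis(pitch)
    slope = np.tan(np.radians(angle_deg))
    return np.clip((x - x0) * slope, 0.0, max_depth)


def build_wound_surface(
    pitch: float = DEFAULT_PITCH,
    bulge_diameter: float = 6.0,
    crater_diameter: float = 2.2,
    bulge_height: float = 0.5,
    crater_floor: float = -0.1,
) -> SurfaceField:
    """Wound-mimicking composite: convex annular bulge with a central crater.

    The bulge rises smoothly (sin^2 taper) from the surround at the outer rim
    to its crest and back to zero at the crater rim; the crater dips below the
    baseline so the central concave region is genuinely depressed.
    """
    x = _axis(pitch)
    xx, yy = np.meshgrid(x, x)
    c = DOMAIN_XY / 2.0
    r = np.hypot(xx - c, yy - c)
    r_out = bulge_diameter / 2.0
    r_in = crater_diameter / 2.0
    h = np.zeros_like(r)
    ring = (r >= r_in) & (r < r_out)
    h[ring] = bulge_height * np.sin(np.pi * (r_out - r[ring]) / (r_out - r_in)) ** 2
    crater = r < r_in
    h[crater] = crater_floor * np.cos(np.pi * r[crater] / (2.0 * r_in)) ** 2
    return SurfaceField(h, pitch)


# ---------------------------------------------------------------------------
# derived maps
# ---------------------------------------------------------------------------

def surface_normals(surface: SurfaceField) -> NormalMap:
    """Outward unit normals from central differences of the height field.

    cos(theta) = 1 / sqrt(1 + hx^2 + hy^2), the cosine of the angle between
    the surface normal and the vertical detection direction.
    """
    hy, hx = np.gradient(surface.heights, surface.pitch)
    norm = np.sqrt(1.0 + hx**2 + hy**2)
    normals = np.stack([-hx / norm, -hy / norm, 1.0 / norm], axis=-1)
    return NormalMap(normals=normals, cos_theta=1.0 / norm)


def depth_map(surface: SurfaceField, focus_z: float = 0.0) -> DepthMap:
    """Vertical distance of each surface pixel below the focused plane."""
    dz = focus_z - surface.heights
    if np.any(dz < -1e-9):
        dz = np.abs(dz)
    return DepthMap(delta_z=np.maximum(dz, 0.0), focus_z=focus_z)
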