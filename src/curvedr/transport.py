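"""Monte-Carlo photon transport through curved layered phantoms.

Weight-based (MCML-style) hop-drop-spin transport with Henyey-Greenstein
scattering, unpolarized Fresnel reflection/refraction at every refractive
boundary, and Russian roulette termination.  The curved air-tissue interface
and the internal layer interfaces (vertical offsets of the top surface) are
resolved by bisecting each free-flight segment whose endpoint lands in a
different medium; free paths in tissue (<= 0.05 cm) are far shorter than any
surface feature, so grazing double crossings within one segment are
negligible.

Photons escaping the top surface into air are ray-marched through the air
gap (they may re-enter the tissue across a concavity - this is the light
trapping that brightens concave bowls) and, once clear of the surface, are
tallied by the collector: a photon contributes to the pixel containing its
surface exit point if its exit ray passes through the lens aperture.  The
acceptance solid angle shrinks as a surface point recedes from the lens
(the height-loss physics the corrections calibrate against) and a tilted
escape lobe sends less weight into the acceptance cone (the angle physics).

Specular light that never enters the tissue is excluded from the diffuse
reflectance image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .geometry import DOMAIN_XY, DOMAIN_Z, TissueModel, _axis

WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
AIR_STEP = 0.05  # cm, ray-march step through air gaps
_AIR = -1

# tally indices
T_ABS, T_TOP, T_OTHER, T_SPEC, T_ROU_KILL, T_ROU_BOOST, T_ABORT = range(7)


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------

@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    medium: str = "ambient"
    alive: bool = True


@dataclass(frozen=True)
class SourceSpec:
    """Uniform collimated or focused-Gaussian illumination.

    For the Gaussian source, ``spatial_width`` is the standard deviation (cm)
    of the symmetric two-dimensional intensity profile in the focused object
    plane -- sigma = 1.5 cm gives the ~3 cm 1/e^2 illumination radius of the
    handheld device being emulated -- and ``angular_width_deg`` is the 1/e^2
    half-angle of the mild angular spread about the vertical.  ``standoff``
    records the device's source height above the object plane (metadata; the
    beam is parameterized directly in the object plane).
    """

    kind: str  # "uniform" | "gaussian"
    wavelength: int
    center: tuple[float, float] = (5.0, 5.0)
    spatial_width: float = 1.5
    angular_width_deg: float = 10.0
    standoff: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise ValueError("source kind must be 'uniform' or 'gaussian'")
        if self.wavelength not in (690, 830):
            raise ValueError("wavelength must be 690 or 830 nm")
        if self.kind == "gaussian" and (
            self.spatial_width <= 0 or self.angular_width_deg <= 0
        ):
            raise ValueError("gaussian source widths must be > 0")


@dataclass(frozen=True)
class CollectorSpec:
    """Ideal thin-lens camera on axis above the field, focused at focus_z."""

    standoff: float = 25.0  # cm, lens height above the focused plane
    aperture: float = 20.0  # cm, lens diameter (wide acceptance cone)
    focus_z: float = 0.0
    center: tuple[float, float] = (5.0, 5.0)
    pitch: float = 0.1
    extent: tuple[float, float] = (DOMAIN_XY, DOMAIN_XY)

    def __post_init__(self) -> None:
        if self.aperture <= 0 or self.standoff <= 0:
            raise ValueError("aperture and standoff must be > 0")

    @property
    def lens_z(self) -> float:
        return self.focus_z + self.standoff


@dataclass
class EscapeEvents:
    """Photons that left the top surface: exit ray and residual weight."""

    position: np.ndarray  # (n, 3)
    direction: np.ndarray  # (n, 3)
    weight: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.weight.size

    def translated(self, dz: float) -> "EscapeEvents":
        """Events as seen when the phantom is rigidly shifted by dz in z."""
        pos = self.position.copy()
        pos[:, 2] += dz
        return EscapeEvents(pos, self.direction, self.weight)


@dataclass
class DRImage:
    """Diffuse-reflectance image: collected weight per pixel / launched."""

    values: np.ndarray
    wavelength: int
    pitch: float = 0.1
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# elementary samplers (canonical formulas, also mirrored inside the kernel)
# ---------------------------------------------------------------------------

def sample_free_path(mu_t: float, rng: np.random.Generator):
    """Exponential free path s = -ln(xi)/mu_t."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    xi = rng.random()
    if xi <= 0.0:
        xi = 1e-300
    return -math.log(xi) / mu_t if xi < 1.0 else 0.0


def scatter_hg(g: float, direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Henyey-Greenstein deflection of a unit direction vector."""
    if abs(g) > 1:
        raise ValueError("|g| must be <= 1")
    xi = rng.random()
    if abs(g) < 1e-6:
        ct = 1.0 - 2.0 * xi
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    ct = min(1.0, max(-1.0, ct))
    phi = 2.0 * math.pi * rng.random()
    ux, uy, uz = _spin(direction[0], direction[1], direction[2], ct, phi)
    return np.array([ux, uy, uz])


def fresnel_interface(
    direction: np.ndarray,
    normal: np.ndarray,
    n1: float,
    n2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Reflect or refract a ray at an interface; returns (direction, reflected)."""
    u = np.asarray(direction, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    if np.dot(u, nrm) > 0:  # orient the normal against the incident ray
        nrm = -nrm
    ci = -float(np.dot(u, nrm))
    R = fresnel_reflectance(ci, n1, n2)
    if rng.random() < R:
        return u - 2.0 * np.dot(u, nrm) * nrm, True
    if abs(n1 - n2) < 1e-12:
        return u.copy(), False
    eta = n1 / n2
    ct = math.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - ci * ci)))
    return eta * u + (eta * ci - ct) * nrm, False


def fresnel_reflectance(ci: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine ci."""
    return _fresnel_R(ci, n1, n2)


def launch_photon(
    source: SourceSpec, rng: np.random.Generator, focus_z: float = 0.0
) -> PhotonState:
    """Sample an initial photon ray for the given source."""
    if source.kind == "uniform":
        pos = np.array(
            [rng.random() * DOMAIN_XY, rng.random() * DOMAIN_XY, focus_z + source.standoff]
        )
        direction = np.array([0.0, 0.0, -1.0])
    else:
        sigma_p = source.spatial_width
        sigma_s = math.tan(math.radians(source.angular_width_deg)) / 2.0
        px = source.center[0] + sigma_p * rng.standard_normal()
        py = source.center[1] + sigma_p * rng.standard_normal()
        pos = np.array([px, py, focus_z])
        sx = sigma_s * rng.standard_normal()
        sy = sigma_s * rng.standard_normal()
        norm = math.sqrt(sx * sx + sy * sy + 1.0)
        direction = np.array([sx / norm, sy / norm, -1.0 / norm])
    return PhotonState(position=pos, direction=direction)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hfield(grid, pitch, x, y):
    ny, nx = grid.shape
    fx = x / pitch - 0.5
    fy = y / pitch - 0.5
    if fx < 0.0:
        fx = 0.0
    elif fx > nx - 1.000001:
        fx = nx - 1.000001
    if fy < 0.0:
        fy = 0.0
    elif fy > ny - 1.000001:
        fy = ny - 1.000001
    ix = int(fx)
    iy = int(fy)
    ix1 = min(ix + 1, nx - 1)
    iy1 = min(iy + 1, ny - 1)
    tx = fx - ix
    ty = fy - iy
    return (
        grid[iy, ix] * (1 - tx) * (1 - ty)
        + grid[iy, ix1] * tx * (1 - ty)
        + grid[iy1, ix] * (1 - tx) * ty
        + grid[iy1, ix1] * tx * ty
    )


@njit(cache=True, inline="always")
def _fresnel_R(ci, n1, n2):
    if ci < 0.0:
        ci = -ci
    if ci > 1.0:
        ci = 1.0
    if abs(n1 - n2) < 1e-12:
        return 0.0
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) * (n1 / n2) * si2
    if st2 >= 1.0:
        return 1.0  # total internal reflection
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, ct, phi):
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm



@njit(cache=True, inline="always")
def _rand(state):
    """xorshift128+ uniform in [0, 1); state is a 2-element uint64 array."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    state[1] = s1
    total = (s1 + s0) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return float(total >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _randn(state):
    """Standard normal via Box-Muller."""
    u1 = _rand(state)
    if u1 <= 0.0:
        u1 = 1e-300
    u2 = _rand(state)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


@njit(cache=True)
def _init_rng(seed):
    """Seed the xorshift state via splitmix64."""
    state = np.empty(2, dtype=np.uint64)
    x = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        z = x
        z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        state[i] = z ^ (z >> np.uint64(31))
    return state


@njit(cache=True, inline="always")
def _hg_cos(g, state):
    xi = _rand(state)
    if abs(g) < 1e-6:
        return 1.0 - 2.0 * xi
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _medium_index(heights, pitch, bnd, x, y, z):
    """-1 in air above surface or below stack, else layer index."""
    h = _hfield(heights, pitch, x, y)
    depth = h - z
    if depth < 0.0:
        return _AIR
    for i in range(bnd.size):
        if depth < bnd[i]:
            return i
    return _AIR


@njit(cache=True, inline="always")
def _surface_normal(hgx, hgy, pitch, x, y):
    gx = _hfield(hgx, pitch, x, y)
    gy = _hfield(hgy, pitch, x, y)
    norm = math.sqrt(1.0 + gx * gx + gy * gy)
    return -gx / norm, -gy / norm, 1.0 / norm


@njit(cache=True, fastmath=True)
def _trace(
    n_photons,
    seed,
    heights,
    hgx,
    hgy,
    pitch,
    h_max,
    bnd,
    mua,
    mus,
    gg,
    nn,
    src_kind,  # 0 uniform, 1 gaussian
    src_cx,
    src_cy,
    src_z,
    sigma_pos,
    sigma_slope,
    tile_hmin,  # per-tile surface height bounds (1-tile safety margin)
    tile_hmax,
    tile_size,
    ex,
    ey,
    ez,
    eux,
    euy,
    euz,
    ew,
    tallies,
):
    state = _init_rng(seed)
    n_ev = 0
    z_escape = h_max + 2.0 * AIR_STEP
    for _ in range(n_photons):
        # --- launch -------------------------------------------------------
        if src_kind == 0:
            x = _rand(state) * DOMAIN_XY
            y = _rand(state) * DOMAIN_XY
            z = z_escape
            ux = 0.0
            uy = 0.0
            uz = -1.0
        else:
            x = src_cx + sigma_pos * _randn(state)
            y = src_cy + sigma_pos * _randn(state)
            z = src_z
            sx = sigma_slope * _randn(state)
            sy = sigma_slope * _randn(state)
            nrm = math.sqrt(sx * sx + sy * sy + 1.0)
            ux = sx / nrm
            uy = sy / nrm
            uz = -1.0 / nrm
            # start the march exactly at the plane clearing the tallest
            # surface feature (forward or backward along the launch ray)
            t0 = (z_escape - z) / uz
            x += ux * t0
            y += uy * t0
            z = z_escape
        w = 1.0
        med = _AIR
        entered = False
        alive = True
        in_air = True
        guard = 0
        exx = x  # most recent surface exit point (tissue -> air crossing)
        exy = y
        exz = z
        while alive:
            guard += 1
            if guard > 2000000 or not (
                math.isfinite(x) and math.isfinite(y) and math.isfinite(z) and w > 0.0
            ):
                tallies[T_ABORT] += w
                break
            if in_air:
                # ------ straight-line march through air ------------------
                if uz > 0.0 and z > h_max + AIR_STEP:
                    if entered:
                        tallies[T_TOP] += w
                        if n_ev < ew.size:
                            ex[n_ev] = exx
                            ey[n_ev] = exy
                            ez[n_ev] = exz
                            eux[n_ev] = ux
                            euy[n_ev] = uy
                            euz[n_ev] = uz
                            ew[n_ev] = w
                            n_ev += 1
                    else:
                        tallies[T_SPEC] += w
                    break
                if z < -DOMAIN_Z or x < -2.0 or x > DOMAIN_XY + 2.0 or y < -2.0 or y > DOMAIN_XY + 2.0:
                    tallies[T_OTHER] += w
                    break
                inside = 0.0 <= x <= DOMAIN_XY and 0.0 <= y <= DOMAIN_XY
                if inside and z <= _hfield(heights, pitch, x, y):
                    # crossed the surface during the previous step: bisect back
                    # along the step (back=0 -> below surface, back=AIR_STEP ->
                    # above, except immediately after a grazing exit)
                    lo = 0.0
                    hi = AIR_STEP
                    for _b in range(30):
                        mid = 0.5 * (lo + hi)
                        xm = x - ux * mid
                        ym = y - uy * mid
                        zm = z - uz * mid
                        if zm <= _hfield(heights, pitch, xm, ym):
                            lo = mid
                        else:
                            hi = mid
                    back = 0.5 * (lo + hi)
                    xc = x - ux * back
                    yc = y - uy * back
                    zc = z - uz * back
                    nx_, ny_, nz_ = _surface_normal(hgx, hgy, pitch, xc, yc)
                    dot = ux * nx_ + uy * ny_ + uz * nz_
                    # oriented normal sn opposes the incident ray
                    sgn = -1.0 if dot > 0.0 else 1.0
                    snx, sny, snz = sgn * nx_, sgn * ny_, sgn * nz_
                    ci = -(ux * snx + uy * sny + uz * snz)
                    n2 = nn[0]
                    R = _fresnel_R(ci, 1.0, n2)
                    if _rand(state) < R:
                        ux -= 2.0 * dot * nx_
                        uy -= 2.0 * dot * ny_
                        uz -= 2.0 * dot * nz_
                        x = xc + ux * 1e-6 + snx * 1e-5
                        y = yc + uy * 1e-6 + sny * 1e-5
                        z = zc + uz * 1e-6 + snz * 1e-5
                    else:
                        eta = 1.0 / n2
                        ct = math.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - ci * ci)))
                        ux = eta * ux + (eta * ci - ct) * snx
                        uy = eta * uy + (eta * ci - ct) * sny
                        uz = eta * uz + (eta * ci - ct) * snz
                        nrm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= nrm
                        uy /= nrm
                        uz /= nrm
                        x = xc + ux * 1e-6 - snx * 1e-5
                        y = yc + uy * 1e-6 - sny * 1e-5
                        z = zc + uz * 1e-6 - snz * 1e-5
                        med = _medium_index(heights, pitch, bnd, x, y, z)
                        if med == _AIR:
                            med = 0
                        entered = True
                        in_air = False
                    continue
                x += ux * AIR_STEP
                y += uy * AIR_STEP
                z += uz * AIR_STEP
                continue
            # ------ tissue hop ------------------------------------------
            xi = _rand(state)
            if xi <= 0.0:
                xi = 1e-300
            tau = -math.log(xi)
            crossings = 0
            while tau > 1e-12 and crossings < 64:
                mt = mua[med] + mus[med]
                s = tau / mt
                xn = x + ux * s
                yn = y + uy * s
                zn = z + uz * s
                if xn < 0.0 or xn > DOMAIN_XY or yn < 0.0 or yn > DOMAIN_XY or zn < -DOMAIN_Z:
                    tallies[T_OTHER] += w
                    alive = False
                    break
                # fast path: if the whole segment provably stays inside the
                # current layer (conservative per-tile height bounds), skip
                # the height-field lookups entirely
                ti = int(x / tile_size)
                tj = int(y / tile_size)
                if ti < 0:
                    ti = 0
                elif ti >= tile_hmin.shape[1]:
                    ti = tile_hmin.shape[1] - 1
                if tj < 0:
                    tj = 0
                elif tj >= tile_hmin.shape[0]:
                    tj = tile_hmin.shape[0] - 1
                z_hi = z if z > zn else zn
                z_lo = z if z < zn else zn
                d_min = tile_hmin[tj, ti] - z_hi  # shallowest possible depth
                d_max = tile_hmax[tj, ti] - z_lo  # deepest possible depth
                b_lo = 0.0 if med == 0 else bnd[med - 1]
                if d_min > b_lo + 1e-9 and d_max < bnd[med] - 1e-9:
                    x = xn
                    y = yn
                    z = zn
                    tau = 0.0
                    break
                d0 = _hfield(heights, pitch, x, y) - z
                dn = _hfield(heights, pitch, xn, yn) - zn
                mn = _AIR
                if dn >= 0.0:
                    mn = bnd.size  # sentinel: below the stack
                    for i in range(bnd.size):
                        if dn < bnd[i]:
                            mn = i
                            break
                if mn == med:
                    x = xn
                    y = yn
                    z = zn
                    tau = 0.0
                    break
                # boundary depth first crossed along the segment
                if mn == _AIR or mn < med:
                    b_cross = 0.0 if med == 0 else bnd[med - 1]
                else:
                    b_cross = bnd[med]
                # regula falsi on g(t) = depth(t) - b_cross over [0, s]
                g0 = d0 - b_cross
                g1 = dn - b_cross
                t_lo = 0.0
                t_hi = s
                for _b in range(4):
                    denom = g1 - g0
                    if abs(denom) < 1e-300:
                        break
                    t_m = t_lo - g0 * (t_hi - t_lo) / denom
                    if t_m <= t_lo or t_m >= t_hi:
                        t_m = 0.5 * (t_lo + t_hi)
                    d_m = (
                        _hfield(heights, pitch, x + ux * t_m, y + uy * t_m)
                        - (z + uz * t_m)
                    )
                    if (d_m - b_cross > 0.0) == (g0 > 0.0):
                        t_lo = t_m
                        g0 = d_m - b_cross
                    else:
                        t_hi = t_m
                        g1 = d_m - b_cross
                xc = x + ux * t_hi
                yc = y + uy * t_hi
                zc = z + uz * t_hi
                dc = _hfield(heights, pitch, xc, yc) - zc
                # medium on the far side of this boundary
                if mn == _AIR or mn < med:
                    m2 = _AIR if med == 0 else med - 1
                else:
                    m2 = med + 1
                tau -= t_hi * mt
                if tau < 0.0:
                    tau = 0.0
                # below the tissue stack: depth-wise air, treat as lost
                if m2 == bnd.size or (mn == bnd.size and dc >= bnd[bnd.size - 1] - 1e-9):
                    tallies[T_OTHER] += w
                    alive = False
                    break
                nx_, ny_, nz_ = _surface_normal(hgx, hgy, pitch, xc, yc)
                dot = ux * nx_ + uy * ny_ + uz * nz_
                sx_, sy_, sz_ = nx_, ny_, nz_
                if dot > 0.0:
                    sx_, sy_, sz_ = -nx_, -ny_, -nz_  # orient against the ray
                ci = -(ux * sx_ + uy * sy_ + uz * sz_)
                n1 = nn[med]
                n2 = 1.0 if m2 == _AIR else nn[m2]
                R = _fresnel_R(ci, n1, n2)
                if _rand(state) < R:
                    ux -= 2.0 * dot * nx_
                    uy -= 2.0 * dot * ny_
                    uz -= 2.0 * dot * nz_
                    x = xc + ux * 1e-6 + sx_ * 1e-5
                    y = yc + uy * 1e-6 + sy_ * 1e-5
                    z = zc + uz * 1e-6 + sz_ * 1e-5
                else:
                    eta = n1 / n2
                    ct = math.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - ci * ci)))
                    ux = eta * ux + (eta * ci - ct) * sx_
                    uy = eta * uy + (eta * ci - ct) * sy_
                    uz = eta * uz + (eta * ci - ct) * sz_
                    nrm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= nrm
                    uy /= nrm
                    uz /= nrm
                    x = xc + ux * 1e-6 - sx_ * 1e-5
                    y = yc + uy * 1e-6 - sy_ * 1e-5
                    z = zc + uz * 1e-6 - sz_ * 1e-5
                    if m2 == _AIR:
                        exx = xc
                        exy = yc
                        exz = zc
                        in_air = True
                        med = _AIR
                        break
                    med = m2
                crossings += 1
            if not alive or in_air:
                continue
            # ------ drop + roulette + spin -------------------------------
            mt = mua[med] + mus[med]
            dw = w * mua[med] / mt
            tallies[T_ABS] += dw
            w -= dw
            if w < WEIGHT_THRESHOLD:
                if _rand(state) < ROULETTE_SURVIVAL:
                    boost = w * (1.0 / ROULETTE_SURVIVAL - 1.0)
                    tallies[T_ROU_BOOST] += boost
                    w /= ROULETTE_SURVIVAL
                else:
                    tallies[T_ROU_KILL] += w
                    break
            ct = _hg_cos(gg[med], state)
            phi = 2.0 * math.pi * _rand(state)
            ux, uy, uz = _spin(ux, uy, uz, ct, phi)
    return n_ev


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------

def _tile_bounds(
    heights: np.ndarray, pitch: float, tile_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Conservative per-tile surface height bounds with a 1-tile margin.

    A free-flight segment is always far shorter than one tile, so the bounds
    of the tile containing the segment start safely bracket the surface over
    the whole segment.
    """
    px = max(1, int(round(tile_size / pitch)))
    ny, nx = heights.shape
    nty = (ny + px - 1) // px
    ntx = (nx + px - 1) // px
    hmin = np.full((nty, ntx), np.inf)
    hmax = np.full((nty, ntx), -np.inf)
    for j in range(nty):
        for i in range(ntx):
            blk = heights[j * px : (j + 1) * px + 1, i * px : (i + 1) * px + 1]
            hmin[j, i] = blk.min()
            hmax[j, i] = blk.max()
    pad_min = np.pad(hmin, 1, mode="edge")
    pad_max = np.pad(hmax, 1, mode="edge")
    out_min = hmin.copy()
    out_max = hmax.copy()
    for dj in range(3):
        for di in range(3):
            out_min = np.minimum(out_min, pad_min[dj : dj + nty, di : di + ntx])
            out_max = np.maximum(out_max, pad_max[dj : dj + nty, di : di + ntx])
    return out_min, out_max


def run_transport(
    model: TissueModel,
    source: SourceSpec,
    n_photons: int,
    seed: int,
    focus_z: float = 0.0,
) -> tuple[EscapeEvents, dict]:
    """Trace photons through the phantom; return top-escape events + tallies."""
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    props = model.properties(source.wavelength)
    mua = np.array([p.mu_a for p in props])
    mus = np.array([p.mu_s for p in props])
    gg = np.array([p.g for p in props])
    nn = np.array([p.n for p in props])
    bnd = model.boundaries.astype(np.float64)
    heights = np.ascontiguousarray(model.surface.heights)
    pitch = model.surface.pitch
    hgy, hgx = np.gradient(heights, pitch)
    hgx = np.ascontiguousarray(hgx)
    hgy = np.ascontiguousarray(hgy)
    h_max = float(heights.max())

    src_kind = 0 if source.kind == "uniform" else 1
    sigma_pos = source.spatial_width
    sigma_slope = math.tan(math.radians(source.angular_width_deg)) / 2.0
    # gaussian beams are parameterized in the focused object plane; the launch
    # ray is traced back above the surface from there
    src_z = focus_z if src_kind == 1 else focus_z + source.standoff

    tile_size = 0.5  # cm
    tile_hmin, tile_hmax = _tile_bounds(heights, pitch, tile_size)

    n = int(n_photons)
    ex = np.empty(n, dtype=np.float32)
    ey = np.empty(n, dtype=np.float32)
    ez = np.empty(n, dtype=np.float32)
    eux = np.empty(n, dtype=np.float32)
    euy = np.empty(n, dtype=np.float32)
    euz = np.empty(n, dtype=np.float32)
    ew = np.empty(n, dtype=np.float32)
    tallies = np.zeros(7)

    n_ev = _trace(
        n,
        int(seed) % (2**31 - 1),
        heights,
        hgx,
        hgy,
        pitch,
        h_max,
        bnd,
        mua,
        mus,
        gg,
        nn,
        src_kind,
        source.center[0],
        source.center[1],
        src_z,
        sigma_pos,
        sigma_slope,
        tile_hmin,
        tile_hmax,
        tile_size,
        ex,
        ey,
        ez,
        eux,
        euy,
        euz,
        ew,
        tallies,
    )
    events = EscapeEvents(
        position=np.stack([ex[:n_ev], ey[:n_ev], ez[:n_ev]], axis=1).astype(np.float64),
        direction=np.stack([eux[:n_ev], euy[:n_ev], euz[:n_ev]], axis=1).astype(
            np.float64
        ),
        weight=ew[:n_ev].astype(np.float64),
    )
    tally = {
        "launched": float(n),
        "absorbed": tallies[T_ABS],
        "escaped_top": tallies[T_TOP],
        "escaped_other": tallies[T_OTHER],
        "specular": tallies[T_SPEC],
        "rouletted": tallies[T_ROU_KILL],
        "roulette_boost": tallies[T_ROU_BOOST],
        "aborted": tallies[T_ABORT],
    }
    return events, tally


def collect_image(
    events: EscapeEvents,
    collector: CollectorSpec,
    n_photons: int,
    wavelength: int,
    meta: Optional[dict] = None,
) -> DRImage:
    """Tally escape rays accepted by the collector onto the pixel grid.

    A photon contributes to the pixel containing its surface exit point
    (projected vertically) if its exit ray passes through the lens aperture.
    The acceptance solid angle shrinks as a surface point recedes from the
    lens, which is the height-loss physics the corrections calibrate; a
    tilted escape lobe sends less weight into the fixed acceptance cone,
    which is the angle physics.
    """
    nx = int(round(collector.extent[0] / collector.pitch))
    ny = int(round(collector.extent[1] / collector.pitch))
    img = np.zeros((ny, nx))
    if len(events) > 0:
        p = events.position
        u = events.direction
        w = events.weight
        up = u[:, 2] > 1e-9
        p, u, w = p[up], u[up], w[up]
        # ray -> lens plane: inside the aperture?
        t_lens = (collector.lens_z - p[:, 2]) / u[:, 2]
        lx = p[:, 0] + u[:, 0] * t_lens - collector.center[0]
        ly = p[:, 1] + u[:, 1] * t_lens - collector.center[1]
        ok = (t_lens > 0) & (lx * lx + ly * ly <= (collector.aperture / 2.0) ** 2)
        p, w = p[ok], w[ok]
        ix = np.floor(p[:, 0] / collector.pitch).astype(np.int64)
        iy = np.floor(p[:, 1] / collector.pitch).astype(np.int64)
        inb = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(img, (iy[inb], ix[inb]), w[inb])
    img /= float(n_photons)
    meta = dict(meta or {})
    meta.update(n_photons=int(n_photons), collector=collector)
    return DRImage(values=img, wavelength=wavelength, pitch=collector.pitch, meta=meta)


def run_simulation(
    model: TissueModel,
    source: SourceSpec,
    collector: CollectorSpec,
    n_photons: int,
    seed: int,
) -> DRImage:
    """Full simulate-and-collect pass; deterministic for a fixed seed."""
    events, tally = run_transport(
        model, source, n_photons, seed, focus_z=collector.focus_z
    )
    img = collect_image(
        events,
        collector,
        n_photons,
        source.wavelength,
        meta={"seed": int(seed), "source": source, "tally": tally},
    )
    return img
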