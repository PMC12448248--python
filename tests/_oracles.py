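"""Independent oracles shared by the test modules.

These deliberately re-derive results through separate code paths (1-D planar
Monte Carlo, brute-force interpolation, Gaussian elimination) so the package
implementations are checked against something other than themselves.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def oracle_slab(mua, mus, g, thickness, n_rel, n_photons, seed):
    """1-D planar-slab MC: (diffuse reflectance, total transmittance)."""
    np.random.seed(seed)
    mt = mua + mus
    albedo = mus / mt
    rd = 0.0
    tt = 0.0
    for _ in range(n_photons):
        w = 1.0
        r0 = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
        w *= 1.0 - r0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        while True:
            s = -math.log(np.random.random() + 1e-300) / mt
            zn = z + uz * s
            if zn < 0.0 or zn > thickness:
                ci = abs(uz)
                st2 = n_rel * n_rel * (1.0 - ci * ci)
                if st2 >= 1.0:
                    refl = 1.0
                else:
                    ct = math.sqrt(1.0 - st2)
                    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                    refl = 0.5 * (rs * rs + rp * rp)
                if np.random.random() < refl:
                    z = 0.0 if zn < 0.0 else thickness
                    uz = -uz
                    continue
                if zn < 0.0:
                    rd += w
                else:
                    tt += w
                break
            z = zn
            w *= albedo
            if w < 1e-4:
                if np.random.random() < 0.1:
                    w *= 10.0
                else:
                    break
            xi = np.random.random()
            if abs(g) < 1e-6:
                ct = 1.0 - 2.0 * xi
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux2 = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy2 = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz2 = -st * cp * den + uz * ct
                ux, uy, uz = ux2, uy2, uz2
    return rd / n_photons, tt / n_photons
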