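"""Modified Beer-Lambert law hemoglobin mapping from two-wavelength DR.

Changes in optical density relative to a simulated white diffusing reference
sheet are converted, pixel by pixel, into relative oxy-/deoxy-hemoglobin
concentration changes by inverting the 2x2 extinction system

    dOD(lambda) = L * [ e_HbO(lambda) * dHbO + e_HbR(lambda) * dHbR ]

at 690 and 830 nm.  The effective pathlength L is left at 1, so the
concentration maps are in arbitrary units; L cancels in StO2 and in the
relative-error comparisons the studies report.  dOD uses the decadic
logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TissueModel, build_flat_surface, build_layered_model
from .optics import calibration_sheet_layers
from .transport import CollectorSpec, DRImage, SourceSpec, run_simulation

# Standard compiled molar extinction coefficients (cm^-1 / M); any common
# tabulation works here because only ratios and relative errors are reported.
DEFAULT_EXTINCTION = {
    690: {"HbO": 276.0, "HbR": 2051.96},
    830: {"HbO": 974.0, "HbR": 693.04},
}

STO2_FLOOR = 1e-9


@dataclass
class ExtinctionTable:
    """2x2 extinction system for (HbO, HbR) at the two wavelengths."""

    values: dict[int, dict[str, float]] = field(
        default_factory=lambda: {wl: dict(v) for wl, v in DEFAULT_EXTINCTION.items()}
    )
    pathlength: float = 1.0  # cm, effective; arbitrary-units convention

    def matrix(self, wavelengths=(690, 830)) -> np.ndarray:
        m = np.array(
            [
                [self.values[wl]["HbO"], self.values[wl]["HbR"]]
                for wl in wavelengths
            ]
        ) * self.pathlength
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        return m


@dataclass
class HemoglobinMaps:
    """Relative hemoglobin concentration maps and oxygen saturation."""

    dHbO: np.ndarray
    dHbR: np.ndarray
    dHbT: np.ndarray
    StO2: np.ndarray  # percent; NaN where invalid
    valid: np.ndarray


def reference_signal(
    source: SourceSpec,
    collector: CollectorSpec,
    n_photons: int,
    seed: int,
    pitch: float = 0.1,
) -> DRImage:
    """DR image of the homogeneous 0.2 cm white calibration sheet."""
    surf = build_flat_surface(pitch)
    model = build_layered_model(surf, calibration_sheet_layers())
    return run_simulation(model, source, collector, n_photons, seed)


def delta_od(image: DRImage, reference: DRImage) -> np.ndarray:
    """Optical-density change dOD = -log10(I / I_ref); NaN where undefined."""
    if image.wavelength != reference.wavelength:
        raise ValueError("image and reference wavelengths differ")
    if image.shape != reference.shape:
        raise ValueError("image and reference grids differ")
    i = image.values
    r = reference.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log10(i / r)
    out[(i <= 0) | (r <= 0)] = np.nan
    return out


def solve_mbll(
    dod690: np.ndarray,
    dod830: np.ndarray,
    ext: ExtinctionTable | None = None,
    sto2_floor: float = STO2_FLOOR,
) -> HemoglobinMaps:
    """Invert the per-pixel 2x2 extinction system for (dHbO, dHbR)."""
    ext = ext or ExtinctionTable()
    if dod690.shape != dod830.shape:
        raise ValueError("dOD maps are not aligned")
    m = ext.matrix()
    minv = np.linalg.inv(m)
    od = np.stack([dod690, dod830], axis=-1)
    hb = np.einsum("ij,...j->...i", minv, od)
    dhbo = hb[..., 0]
    dhbr = hb[..., 1]
    dhbt = dhbo + dhbr
    valid = np.isfinite(dhbt)
    sto2 = sto2_map_arrays(dhbo, dhbt, sto2_floor)
    return HemoglobinMaps(dHbO=dhbo, dHbR=dhbr, dHbT=dhbt, StO2=sto2, valid=valid)


def sto2_map_arrays(dhbo: np.ndarray, dhbt: np.ndarray, floor: float = STO2_FLOOR):
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = 100.0 * dhbo / dhbt
    sto2 = np.where(np.abs(dhbt) > floor, sto2, np.nan)
    return sto2


def sto2_map(maps: HemoglobinMaps, floor: float = STO2_FLOOR) -> np.ndarray:
    """Oxygen saturation percent map, invalid where |dHbT| is below floor."""
    return sto2_map_arrays(maps.dHbO, maps.dHbT, floor)


def hemoglobin_from_images(
    img690: DRImage,
    img830: DRImage,
    ref690: DRImage,
    ref830: DRImage,
    ext: ExtinctionTable | None = None,
) -> HemoglobinMaps:
    """Full MBLL chain: dOD against the reference sheet, then the 2x2 solve."""
    return solve_mbll(delta_od(img690, ref690), delta_od(img830, ref830), ext)
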