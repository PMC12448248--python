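"""Optical properties of the layered skin phantom.

The three-layer phantom (epidermis / dermis / subcutis) mimics Fitzpatrick
type-2 skin at the two NIRS wavelengths (690 and 830 nm).  A thin highly
scattering "calibration sheet" slab serves as the white reference for the
modified Beer-Lambert law.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/scattering properties of one medium at one wavelength.

    mu_a, mu_s in 1/cm; g is the Henyey-Greenstein anisotropy factor;
    n the refractive index.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (1/cm)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: thickness (cm) and per-wavelength properties."""

    name: str
    thickness: float
    props: dict[int, OpticalProperties] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")

    def at(self, wavelength: int) -> OpticalProperties:
        try:
            return self.props[int(wavelength)]
        except KeyError:
            raise KeyError(
                f"layer {self.name!r} has no optical properties at {wavelength} nm"
            ) from None


AMBIENT = OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0, n=1.0)

WAVELENGTHS = (690, 830)


def skin_layers() -> list[LayerSpec]:
    """Literature three-layer skin model used throughout the studies."""
    return [
        LayerSpec(
            "epidermis",
            0.0206,
            {
                690: OpticalProperties(4.9403, 161.1201, 0.8201, 1.431),
                830: OpticalProperties(2.6727, 172.9819, 0.8607, 1.431),
            },
        ),
        LayerSpec(
            "dermis",
            0.30,
            {
                690: OpticalProperties(0.37159, 105.1904, 0.8201, 1.378),
                830: OpticalProperties(0.42059, 94.5299, 0.8607, 1.378),
            },
        ),
        LayerSpec(
            "subcutis",
            3.6794,
            {
                690: OpticalProperties(1.15, 147.3016, 0.96, 1.44),
                830: OpticalProperties(1.05, 131.5236, 0.96, 1.44),
            },
        ),
    ]


def calibration_sheet_layers() -> list[LayerSpec]:
    """Homogeneous white diffusing reference slab (0.2 cm)."""
    return [
        LayerSpec(
            "calibration_sheet",
            0.2,
            {
                690: OpticalProperties(0.20, 200.0, 0.90, 1.40),
                830: OpticalProperties(0.10, 150.0, 0.90, 1.40),
            },
        ),
    ]
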