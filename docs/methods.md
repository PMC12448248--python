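# Methods

`curvedr` simulates wide-field near-infrared diffuse-reflectance (DR) imaging
of layered skin phantoms with curved top surfaces and implements four
curvature-correction models, a modified Beer–Lambert (MBLL) hemoglobin
mapping chain, and the relative-error analysis that quantifies how well each
correction restores the flat-surface signal. This note records the model, its
assumptions, the numerical choices, and what the synthetic studies do and do
not establish.

## Phantom model

The phantom is a 10 × 10 × 6 cm³ block whose top surface is a height field
h(x, y) over a regular pixel grid (default pitch 0.1 cm for study images;
0.05 cm for wedge calibrations and geometry tests). Below the surface sit
three layers — epidermis (0.0206 cm), dermis (0.30 cm), subcutis (3.6794 cm)
— with literature absorption/scattering coefficients, Henyey–Greenstein
anisotropy and refractive indices at 690 and 830 nm, emulating Fitzpatrick
type-2 skin. Layers are vertical offsets of the top surface: thickness is
measured along z, not along the local normal — an approximation that is exact
on flat regions and adequate for the gentle slopes that carry most of the
signal. Layer intervals in depth-below-surface are closed below, open above,
so a point exactly on the surface is epidermis.

Surfaces: flat; spherical caps (convex bump / concave bowl) of radius
1.5–3.5 cm with a 5 cm footprint, clamped to the sphere diameter with a
warning when the footprint is geometrically impossible; descending wedges
(inclined planes) for the empirical calibration; and a wound-mimicking
composite — a sin²-tapered convex annular bulge (outer diameter 6 cm, crest
height 0.5 cm) around a central crater (diameter 2.2 cm) whose floor dips
0.1 cm below the surround. The crater floor is placed below the baseline so
that the convex-structure mask (h > 0) used by the wound workflow excludes
the depressed center by construction; only the bulge and crater diameters
are fixed inputs, the crest height and crater depth are this package's
defaults.

## Photon transport

Weight-based (MCML-style) hop–drop–spin Monte Carlo: exponential free paths
s = −ln ξ / μt, per-interaction weight deposit w·μa/μt, Henyey–Greenstein
scattering, unpolarized Fresnel reflection/refraction at every refractive
boundary (air–tissue across the curved surface, and the internal layer
interfaces), and Russian roulette below weight 10⁻⁴ with survival probability
1/10. Curved-boundary crossings are found by comparing the medium at the two
ends of each free-flight segment and locating the crossing with a few
regula-falsi iterations on the depth-below-surface; free paths in tissue
(≤ ~0.05 cm) are far shorter than any surface feature, so double crossings
within one segment are negligible. A conservative per-tile bound on the
surface height lets most steps skip the height-field lookups entirely.
Photons that escape the top surface are ray-marched through the air gap and
may re-enter the tissue across a concavity — this light trapping is what
brightens concave bowls. Photons leaving the domain laterally or through the
bottom are dropped; specular light that never enters the tissue is excluded
from the DR image. Weight bookkeeping is exact: absorbed + escaped +
specular + roulette-killed − roulette-boost equals the launched weight to
1 part in 10⁹ (tested).

Randomness is a single sequential xorshift128+ stream (splitmix64-seeded)
per run; results are bit-reproducible for a fixed seed.

## Sources

* Uniform: collimated (−ẑ), uniform over the full field — used for the
  calibrations, so illumination is translation-invariant and the illumination
  angle equals the surface tilt.
* Gaussian: the handheld-device beam, parameterized in the focused object
  plane as a symmetric 2-D Gaussian with σ = 1.5 cm (1/e² radius 3 cm,
  matching the device's ~3 cm illumination radius) and a mild angular spread
  (1/e² half-angle 10°). The σ reading matters: treating 1.5 cm as a beam
  waist with divergence wide enough to give a 3 cm spot would dilute the
  illumination several-fold over 0–3 cm of depth, which is incompatible with
  the observed brightening of concave bowls.

## Collector

An ideal lens of diameter 20 cm on axis 25 cm above the focused plane. A
photon contributes to the image pixel containing its surface exit point if
its exit ray passes through the aperture. Two pieces of physics follow: a
surface point a distance Δz below the focused plane sees a smaller acceptance
solid angle (≈ (D/(D+Δz))², the height loss), and a tilted surface emits an
escape lobe rotated away from the acceptance cone (the angle loss). A
radiance-conserving imaging collector would *not* show the height loss for an
extended uniformly lit surface (brightness theorem), which is why the exit-
pixel tally is used; it corresponds to tallying per surface element with a
finite-aperture acceptance, as voxel-based MC light collectors do. The lens
distance is not a constrained device parameter (only the 2 cm
source-to-plane distance is); 25 cm was chosen so that the height factor
spans a clearly quadratic range over 0–3 cm. The wide aperture (acceptance
half-angle ~22°) is a desk-scale feasibility choice: it collects ~14 % of
the escaping diffuse light, without which the hemoglobin error medians are
statistically unresolvable at single-CPU photon counts; a narrower cone
sharpens the angular discrimination and steepens the angle factors. All
corrections are calibrated and applied within the same collector model, so
the pipeline is self-consistent for any aperture.

The collector is focused on the **top plane of each phantom** (focus_z =
max h): every surface point then lies at Δz ≥ 0 *below* the focused plane,
the regime the calibrations probe. For flat and concave phantoms this is the
baseline z = 0. The alternative (focusing on the flat surround of a convex
phantom) would place the cap *above* the focal plane, where a distance-based
collector brightens rather than dims — applying corrections calibrated on
receding surfaces there overcorrects by construction.

## Correction models

1. **Height**: corrected = raw × ε(Δz). ε is calibrated by translating the
   flat phantom 0–3 cm below the focused plane in 0.1 cm steps under the
   uniform source and taking the ratio of interior-mean signals; a quadratic
   is fitted (R² reported). Because a rigid translation under a collimated
   uniform source translates every escape event rigidly, one transport run
   per wavelength is re-collected at all 31 displacements — exact, and it
   removes almost all Monte-Carlo scatter from the ε ratios.
2. **Lambertian angle**: corrected = raw / cos θ, with θ from
   central-difference surface normals; pixels steeper than cos θ = 0.17
   (~80°) are masked instead of divided.
3. **Height + angle**: the exact pixelwise composition of 1 and 2.
4. **Empirical**: corrected = raw / ρ(θ, Δz), ρ tabulated on the 13 × 11 grid
   θ ∈ {0, 5, …, 60}°, Δz ∈ {0, 0.1, …, 1.0} cm from wedge phantoms under the
   uniform source, bilinearly interpolated and clamped to the grid (clamp
   counts logged). At desk-scale photon counts the per-depth-bin ratios on a
   wedge are photon-starved, so each wedge contributes one flat-signal-
   weighted angular factor A(θ) (ratio of inclined to height-compensated flat
   signal over all incline columns, skipping ~2 pixels at the creases where
   finite-difference normals are smeared) and the table row is A(θ)/ε(Δz).
   This constrains the table to be separable in angle and depth; the
   non-separable residual is below the desk-scale noise floor. A(θ) is
   additionally constrained to be non-increasing in θ (pool-adjacent-
   violators), and — because the escape lobe that sets it is fixed by the
   refractive indices, which are identical at both wavelengths in this
   tissue model — A(θ) is estimated from the pooled 690 + 830 nm wedge
   simulations and shared by both wavelengths, while each wavelength keeps
   its own height factor. Sharing removes the cross-wavelength calibration
   noise that the MBLL inversion amplifies roughly thirty-fold into the
   hemoglobin maps. The θ = 0 row is the pure height factor anchored at the
   measured ρ(0, 0); wedges whose incline cannot reach 1 cm inside the field
   (θ = 5°) are covered by the same construction.

Every correction maps the curved-surface signal *toward* the flat baseline
(ε ≥ 1 multiplies, cos θ ≤ 1 and ρ ≤ 1 divide); all are identities on a flat
surface at the focused plane. On the wound phantom, corrections are applied
to the convex structure (h > 0) only; the depressed crater is left
uncorrected.

## Hemoglobin mapping

ΔOD = −log₁₀(I/I_ref) per pixel against a simulated white diffusing reference
slab (0.2 cm, the calibration-sheet optical properties) imaged with the same
Gaussian source, so the illumination profile cancels. The 2 × 2 extinction
system at 690/830 nm is inverted per pixel for (ΔHbO, ΔHbR); ΔHbT is their
sum and StO₂ = 100·ΔHbO/ΔHbT where |ΔHbT| > 10⁻⁹. Extinction coefficients
are the standard compiled molar values (690 nm: HbO₂ 276.0, Hb 2051.96;
830 nm: HbO₂ 974.0, Hb 693.04 cm⁻¹ M⁻¹), overridable; the effective
pathlength is 1, so concentrations are in arbitrary units that cancel in
StO₂ and in all relative errors.

## Error analysis

Relative percentage error = 100·(flat − test)/flat per pixel: convex deficit
positive, concave excess negative. Summary statistics are medians over valid
interior pixels, excluding 0.5 cm at every field edge; the median over the
curved-region footprint is also reported as a secondary column. Error maps
are computed on block-averaged 0.5 cm analysis pixels so that per-pixel
ratios are well resolved at desk-scale counts, and pixels whose flat-phantom
signal is below 10⁻³ of its peak are invalid — this keeps the analysis
region (hence the median) stable against photon count instead of slowly
expanding into the unilluminated corners as statistics accumulate. Hemoglobin
error medians are computed on coarser 1 cm analysis pixels over a stricter
illuminated mask (flat signal above 5 % of peak at both wavelengths),
because the decadic log in ΔOD amplifies shot noise far more than the DR
ratios do; pixels whose |ΔHbT| falls below a quarter of the map's median
magnitude are excluded as unstable (StO₂ is a quotient of two small numbers
there).

## Problem sizes

The studies these pipelines emulate were run at 10⁹ photons per simulation on
a cluster. The package defaults are desk-scale, chosen to run the full
acceptance pipeline on a single CPU: 2 × 10⁶ photons per study image,
4 × 10⁵ per height-calibration transport (re-collected at 31 planes),
2.5 × 10⁵ per wedge and wavelength, 5 × 10⁵ per reference slab; the test
suite uses slightly smaller counts. At these sizes the DR error medians
carry a Monte-Carlo scatter of roughly ±0.5–1 percentage point and the
hemoglobin error medians ±1–2 points.

## What the synthetic studies show — and don't

The phantoms are ideal: exact geometry, homogeneous layers, no measurement
noise in the height/normal maps, and corrections are calibrated inside the
same transport + collector model they are applied in. Passing tests therefore
demonstrate internal consistency of the correction methodology — that the
empirical height/angle table restores convex and wound DR signals and StO₂
maps toward flat-surface values within the stated tolerances — not field
performance on real tissue, where optical properties vary spatially, depth
maps come from noisy stereo reconstruction, and the device geometry differs
from the simulated collector. The concave phantom is the known hard case:
signal converges and corrections can only overcorrect; the package reproduces
that qualitative behaviour, though the balance between bowl trapping
(brightening) and acceptance loss (dimming) depends on the unreported camera
distance, so the concave median's sign is sensitive to that choice.

## Known limitations

* No polarization, fluorescence, or time-resolved transport; height-field
  surfaces only (no overhangs); single-threaded kernel.
* The collector is an idealized acceptance model, not a lens with defocus
  blur; blur-driven signal spreading is absent.
* Layer interfaces are vertical offsets of the top surface; at steep slopes
  the epidermis is locally thicker along the normal than its nominal value.
* Empirical-table separability is imposed by the estimator at desk scale; a
  strongly non-separable θ × Δz coupling would be missed.
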