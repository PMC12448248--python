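"""Relative-percentage-error maps, edge-excluded medians, profiles.

The error convention is

    error = 100 * (flat - test) / flat   [percent]

so a signal deficit on a curved surface (convex dimming) gives a positive
error and a signal excess (concave brightening) a negative one.  Summary
medians exclude a 0.5 cm border of the field (edge effects) and any invalid
pixels (non-positive flat signal, masked corrections).
"""

from __future__ import annotations

import numpy as np

EDGE_MARGIN_DEFAULT = 0.5  # cm


def downsample(values: np.ndarray, pitch: float, bin_cm: float) -> np.ndarray:
    """NaN-aware block-mean downsampling to bin_cm analysis pixels."""
    f = int(round(bin_cm / pitch))
    if f <= 1:
        return values.copy()
    ny, nx = values.shape
    if ny % f or nx % f:
        raise ValueError("bin size must divide the grid")
    blocks = values.reshape(ny // f, f, nx // f, f)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=(1, 3))
    return out


def downsample_mask(mask: np.ndarray, pitch: float, bin_cm: float) -> np.ndarray:
    """A binned pixel belongs to the region if most of its area does."""
    return downsample(mask.astype(float), pitch, bin_cm) > 0.5


def relative_error_map(
    flat: np.ndarray, test: np.ndarray, floor_frac: float = 0.0
) -> np.ndarray:
    """Per-pixel relative percentage error; NaN where undefined.

    ``floor_frac`` optionally invalidates pixels whose reference signal is
    below that fraction of the reference maximum.  The study workflows use a
    small floor so that the valid-pixel set (hence the reported median) is
    stable against the photon count instead of slowly expanding into the
    unilluminated corners as statistics accumulate.
    """
    if flat.shape != test.shape:
        raise ValueError("grids are not aligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        err = 100.0 * (flat - test) / flat
    floor = floor_frac * np.nanmax(flat) if floor_frac > 0 else 0.0
    err = np.where(flat > floor, err, np.nan)
    return err


def median_error(
    error_map: np.ndarray,
    pitch: float,
    margin: float = EDGE_MARGIN_DEFAULT,
    region: np.ndarray | None = None,
) -> float:
    """Median error over valid interior pixels (optionally within a region)."""
    ny, nx = error_map.shape
    # whole analysis pixels are excluded; a margin smaller than one pixel
    # still drops the border row/column
    k = int(np.ceil(margin / pitch - 1e-9))
    if 2 * k >= min(ny, nx):
        raise ValueError("margin leaves no interior pixels")
    sel = np.zeros_like(error_map, dtype=bool)
    sel[k : ny - k, k : nx - k] = True
    if region is not None:
        sel &= region
    sel &= np.isfinite(error_map)
    if not sel.any():
        raise ValueError("no valid pixels for the median")
    return float(np.median(error_map[sel]))


def profile_extract(
    map2d: np.ndarray, axis: str, position: float, pitch: float
) -> np.ndarray:
    """Row/column of the map at the pixel nearest the stated coordinate (cm)."""
    ny, nx = map2d.shape
    idx = int(position / pitch)
    if axis == "y":  # profile along y at fixed x
        if not 0 <= idx < nx:
            raise ValueError("position outside the field")
        return map2d[:, idx].copy()
    if axis == "x":
        if not 0 <= idx < ny:
            raise ValueError("position outside the field")
        return map2d[idx, :].copy()
    raise ValueError("axis must be 'x' or 'y'")
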