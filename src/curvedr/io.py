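"""Artifact persistence: npz containers, CSV tables, 32-bit TIFF exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .correction import EmpiricalCorrectionTable, HeightCorrectionModel
from .geometry import SurfaceField
from .transport import DRImage


def _jsonable(meta: dict) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return repr(o)

    return json.dumps(meta, default=default)


def save_drimage(path, image: DRImage) -> None:
    np.savez_compressed(
        path,
        values=image.values,
        wavelength=image.wavelength,
        pitch=image.pitch,
        meta=_jsonable(image.meta),
    )


def load_drimage(path) -> DRImage:
    with np.load(path, allow_pickle=False) as d:
        return DRImage(
            values=d["values"],
            wavelength=int(d["wavelength"]),
            pitch=float(d["pitch"]),
            meta=json.loads(str(d["meta"])),
        )


def export_image_tiff(path, image: DRImage) -> None:
    tifffile.imwrite(path, image.values.astype(np.float32))


def save_surface(path, surface: SurfaceField) -> None:
    np.savez_compressed(
        path, heights=surface.heights, pitch=surface.pitch, extent=np.array(surface.extent)
    )


def load_surface(path) -> SurfaceField:
    with np.load(path, allow_pickle=False) as d:
        return SurfaceField(
            heights=d["heights"],
            pitch=float(d["pitch"]),
            extent=tuple(d["extent"].tolist()),
        )


def export_heights_tiff(path, surface: SurfaceField) -> None:
    tifffile.imwrite(path, surface.heights.astype(np.float32))


def load_heights_tiff(path, pitch: float) -> SurfaceField:
    return SurfaceField(heights=tifffile.imread(path).astype(np.float64), pitch=pitch)


def save_height_model(path, model: HeightCorrectionModel) -> None:
    wls = sorted(model.coeffs)
    np.savez_compressed(
        path,
        wavelengths=np.array(wls),
        coeffs=np.stack([model.coeffs[w] for w in wls]),
        samples=np.stack([model.samples[w] for w in wls]),
        r2=np.array([model.r2[w] for w in wls]),
        dz_range=np.array(model.dz_range),
    )


def load_height_model(path) -> HeightCorrectionModel:
    with np.load(path, allow_pickle=False) as d:
        wls = [int(w) for w in d["wavelengths"]]
        return HeightCorrectionModel(
            coeffs={w: d["coeffs"][i] for i, w in enumerate(wls)},
            samples={w: d["samples"][i] for i, w in enumerate(wls)},
            r2={w: float(d["r2"][i]) for i, w in enumerate(wls)},
            dz_range=tuple(d["dz_range"].tolist()),
        )


def save_height_csv(path, model: HeightCorrectionModel) -> None:
    """Human-readable height calibration: samples and quadratic coefficients."""
    rows = []
    for wl in sorted(model.coeffs):
        a, b, c = model.coeffs[wl]
        for dz, eps in model.samples[wl]:
            rows.append(
                dict(wavelength=wl, dz_cm=dz, eps=eps, a=a, b=b, c=c, r2=model.r2[wl])
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_table_csv(path, table: EmpiricalCorrectionTable, wavelength: int) -> None:
    df = pd.DataFrame(
        table.rho[int(wavelength)],
        index=pd.Index(table.theta_grid, name="theta_deg"),
        columns=[f"{d:.1f}" for d in table.dz_grid],
    )
    df.to_csv(path)


def load_table_csv(paths_by_wavelength: dict[int, str]) -> EmpiricalCorrectionTable:
    rho = {}
    theta = dz = None
    for wl, path in paths_by_wavelength.items():
        df = pd.read_csv(path, index_col=0)
        rho[int(wl)] = df.to_numpy(dtype=float)
        theta = df.index.to_numpy(dtype=float)
        dz = np.array([float(c) for c in df.columns])
    return EmpiricalCorrectionTable(rho=rho, theta_grid=theta, dz_grid=dz)
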