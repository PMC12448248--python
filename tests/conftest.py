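"""Shared fixtures: surrogate calibrations and desk-scale MC study bundles.

The Monte-Carlo study fixtures are session-scoped because the transport runs
dominate the suite's runtime; every test that consumes them states which
physical quantity it checks.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

logging.getLogger("curvedr").setLevel(logging.ERROR)

# desk-scale problem sizes for the MC study fixtures
N_IMAGE = 1_200_000
N_HEIGHT = 250_000
N_WEDGE = 150_000
N_REFERENCE = 400_000
SEED = 20260928


@pytest.fixture(scope="session")
def surrogate_cal():
    from curvedr.surrogate import surrogate_calibration

    return surrogate_calibration()


@pytest.fixture(scope="session")
def skin_flat_model():
    from curvedr.geometry import build_flat_surface, build_layered_model
    from curvedr.optics import skin_layers

    return build_layered_model(build_flat_surface(pitch=0.1), skin_layers())


@pytest.fixture(scope="session")
def small_flat_run(skin_flat_model):
    """A small uniform-source transport run on the flat skin phantom."""
    from curvedr.transport import SourceSpec, run_transport

    events, tally = run_transport(
        skin_flat_model, SourceSpec("uniform", 690), 30_000, seed=SEED
    )
    return events, tally


@pytest.fixture(scope="session")
def mc_calibrations():
    """Height + empirical calibrations at 690 and 830 nm (desk scale)."""
    from curvedr.workflows import run_calibrations

    return run_calibrations(
        SEED, n_height=N_HEIGHT, n_wedge=N_WEDGE, wavelengths=(690, 830)
    )


@pytest.fixture(scope="session")
def study_bundle(mc_calibrations):
    """Study I and II tables at desk scale, sharing one set of simulations."""
    from curvedr.workflows import study_one, study_two

    images: dict = {}
    flat_images: dict = {}
    geometries = (("concave", 2.5), ("convex", 2.5), ("wound", 0.0))
    df1 = study_one(
        SEED,
        geometries=geometries,
        wavelengths=(690,),
        n_image=N_IMAGE,
        calibrations=mc_calibrations,
        flat_images=flat_images,
        images=images,
    )
    df2 = study_two(
        SEED,
        geometries=(("wound", 0.0),),
        n_image=N_IMAGE,
        n_reference=N_REFERENCE,
        calibrations=mc_calibrations,
        flat_images=flat_images,
        images=images,
    )
    return {"study1": df1, "study2": df2}


def median_of(df, **filters) -> float:
    sel = np.ones(len(df), dtype=bool)
    for k, v in filters.items():
        sel &= df[k] == v
    rows = df[sel]
    assert len(rows) == 1, f"filters {filters} matched {len(rows)} rows"
    return float(rows["median_interior"].iloc[0])
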