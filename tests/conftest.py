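"""Shared fixtures.

The expensive fixtures (a matured 64³ growth run and the curvature benchmark
meshes) are session-scoped: several tests interrogate different statistics of
the same physical object, and the simulations dominate suite runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from nestgrowth import (GrowthConfig, curvatures, d_for_wavelength, dominant_scale,
                        extract_isosurface, gyroid_volume, init_white_noise, run,
                        sphere_volume, summarize)

#: seed used for every stochastic fixture in the suite
SUITE_SEED = 20250925

#: study conditions of the matured-pattern run: triply periodic 64³ grid,
#: white noise of amplitude 0.1 about f0 = 0.5, d chosen for a most-unstable
#: wavelength of 12 cells, integrated for 30 linear-growth timescales.
MATURED_SHAPE = (64, 64, 64)
MATURED_WAVELENGTH = 12.0
MATURED_TIMESCALES = 30.0


@pytest.fixture(scope="session")
def matured_run():
    """Matured white-noise pattern plus its config and linear summary."""
    d = d_for_wavelength(MATURED_WAVELENGTH)
    cfg = GrowthConfig(d=d, rng_seed=SUITE_SEED)
    summary = summarize(d)
    field = init_white_noise(MATURED_SHAPE, cfg)
    result = run(field, cfg, t_end=MATURED_TIMESCALES * summary.timescale)
    return {"field": result.final, "cfg": cfg, "summary": summary}


@pytest.fixture(scope="session")
def matured_mesh(matured_run):
    """Iso-surface of the matured pattern, coordinates rescaled by the FFT length."""
    field = matured_run["field"]
    _, l_dom = dominant_scale(field)
    mesh = curvatures(extract_isosurface(field, 0.5, rescale_length=l_dom))
    return {"mesh": mesh, "dominant_length": l_dom}


@pytest.fixture(scope="session")
def sphere_mesh():
    """Curvature-annotated mesh of a radius-20 ball on a 64³ grid."""
    radius = 20.0
    mesh = curvatures(extract_isosurface(sphere_volume((64, 64, 64), radius), 0.5))
    return {"mesh": mesh, "radius": radius}


@pytest.fixture(scope="session")
def gyroid_mesh():
    """Curvature-annotated gyroid mesh (96³, unit-cell period 16 cells)."""
    wavelength = 16.0
    vol = gyroid_volume((96, 96, 96), wavelength)
    mesh = curvatures(extract_isosurface(vol, 0.5, rescale_length=wavelength))
    return {"mesh": mesh, "wavelength": wavelength, "volume": vol}
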