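"""Synthetic benchmark volumes for calibrating and testing the morphometrics.

Two reference surfaces frame the curvature statistics of nests:

* a **gyroid**, the triply periodic minimal surface
  sin x cos y + sin y cos z + sin z cos x = 0 — zero mean curvature
  everywhere, negative Gaussian curvature almost everywhere;
* **band-passed white noise** — a random surface with a single characteristic
  length but no curvature organization, the null model for "a length scale
  without structure".

Calibration fixtures (sphere, plane, single cosine mode) have closed-form
curvatures and spectra.  All volumes use the same container and value
convention as simulation snapshots (material ≈ 1, empty ≈ 0, surface at 0.5),
so every analysis tool is agnostic to a volume's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import ScalarField3D

__all__ = ["BenchmarkSpec", "make_volume", "gyroid_volume", "bandpass_noise_volume",
           "sphere_volume", "plane_volume", "cosine_mode_volume"]

_MIN_WAVELENGTH_CELLS = 6


@dataclass(frozen=True)
class BenchmarkSpec:
    """Declarative description of one synthetic volume.

    ``params`` per kind:
      gyroid: wavelength (grid-length units)
      bandpass_noise: center_length, relative_width (default 0.25)
      sphere: radius, optional transition_width
      plane: optional z0, transition_width
      cosine_mode: mode (integer counts per axis), amplitude
    """

    kind: str
    shape: tuple[int, int, int]
    spacing: float = 1.0
    params: dict = dc_field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        kinds = ("gyroid", "bandpass_noise", "sphere", "plane", "cosine_mode")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def _grid(shape, spacing):
    axes = [np.arange(n) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def gyroid_volume(shape, wavelength: float, spacing: float = 1.0) -> ScalarField3D:
    """Gyroid phase field: the 0.5 iso-surface is the minimal surface g = 0.

    g = sin qx cos qy + sin qy cos qz + sin qz cos qx with q = 2π/wavelength,
    mapped affinely to [0, 1] (g ranges over ±1.5), so level 0.5 is exactly
    the zero set.
    """
    if wavelength < _MIN_WAVELENGTH_CELLS * spacing:
        raise ValueError(f"wavelength must span >= {_MIN_WAVELENGTH_CELLS} grid cells")
    q = 2.0 * np.pi / wavelength
    x, y, z = _grid(shape, spacing)
    g = (np.sin(q * x) * np.cos(q * y) + np.sin(q * y) * np.cos(q * z)
         + np.sin(q * z) * np.cos(q * x))
    return ScalarField3D(0.5 + g / 3.0, spacing=spacing)


def bandpass_noise_volume(shape, center_length: float, relative_width: float = 0.25,
                          spacing: float = 1.0, rng_seed: int = 0) -> ScalarField3D:
    """Seeded white noise filtered by a Gaussian annulus around 2π/center_length.

    The annulus has standard deviation ``relative_width``·k_c; the DC mode is
    removed and the result is mapped to [0, 1] with mean 0.5.
    """
    if center_length < _MIN_WAVELENGTH_CELLS * spacing:
        raise ValueError(f"center_length must span >= {_MIN_WAVELENGTH_CELLS} grid cells")
    if not 0.0 < relative_width < 1.0:
        raise ValueError("relative_width must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(shape)
    F = np.fft.fftn(noise)
    freqs = [2.0 * np.pi * np.fft.fftfreq(n, d=spacing) for n in shape]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)
    kc = 2.0 * np.pi / center_length
    filt = np.exp(-0.5 * ((kmag - kc) / (relative_width * kc)) ** 2)
    filt_flat = filt.reshape(-1)
    filt_flat[0] = 0.0  # no DC
    y = np.fft.ifftn(F * filt).real
    return ScalarField3D(0.5 + 0.5 * y / np.abs(y).max(), spacing=spacing)


def sphere_volume(shape, radius: float, spacing: float = 1.0,
                  transition_width: float | None = None) -> ScalarField3D:
    """Solid ball: f falls linearly from 1 to 0 across a thin shell at r = R.

    The ramp (default width 4 h) keeps the marching-cubes surface on the exact
    sphere r = R instead of a voxel staircase, so closed-form curvatures
    H = 1/R, Γ = 1/R² are recoverable.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    w = 4.0 * spacing if transition_width is None else transition_width
    center = [(n - 1) / 2.0 * spacing for n in shape]
    x, y, z = _grid(shape, spacing)
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    return ScalarField3D(np.clip(0.5 - (r - radius) / w, 0.0, 1.0), spacing=spacing)


def plane_volume(shape, spacing: float = 1.0, z0: float | None = None,
                 transition_width: float | None = None) -> ScalarField3D:
    """Half-space (material below z0) with a linear ramp: a flat test surface."""
    w = 4.0 * spacing if transition_width is None else transition_width
    if z0 is None:
        z0 = (shape[2] - 1) / 2.0 * spacing
    _, _, z = _grid(shape, spacing)
    values = np.clip(0.5 - (z - z0) / w, 0.0, 1.0) * np.ones([n for n in shape[:2]] + [1])
    return ScalarField3D(np.broadcast_to(values, shape).copy(), spacing=spacing)


def cosine_mode_volume(shape, mode=(1, 0, 0), amplitude: float = 0.25,
                       spacing: float = 1.0, f0: float = 0.5) -> ScalarField3D:
    """Single exact grid mode f = f0 + a·cos(k·x); k_i = 2π m_i /(N_i h)."""
    x, y, z = _grid(shape, spacing)
    ks = [2.0 * np.pi * m / (n * spacing) for m, n in zip(mode, shape)]
    values = f0 + amplitude * np.cos(ks[0] * x + ks[1] * y + ks[2] * z)
    return ScalarField3D(np.broadcast_to(values, shape).copy(), spacing=spacing)


def make_volume(spec: BenchmarkSpec) -> ScalarField3D:
    """Materialize a :class:`BenchmarkSpec` into a phase-field volume."""
    p = spec.params
    if spec.kind == "gyroid":
        return gyroid_volume(spec.shape, p["wavelength"], spec.spacing)
    if spec.kind == "bandpass_noise":
        return bandpass_noise_volume(spec.shape, p["center_length"],
                                     p.get("relative_width", 0.25),
                                     spec.spacing, spec.rng_seed)
    if spec.kind == "sphere":
        return sphere_volume(spec.shape, p["radius"], spec.spacing,
                             p.get("transition_width"))
    if spec.kind == "plane":
        return plane_volume(spec.shape, spec.spacing, p.get("z0"),
                            p.get("transition_width"))
    if spec.kind == "cosine_mode":
        return cosine_mode_volume(spec.shape, p.get("mode", (1, 0, 0)),
                                  p.get("amplitude", 0.25), spec.spacing,
                                  p.get("f0", 0.5))
    raise ValueError(f"unknown kind {spec.kind!r}")
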