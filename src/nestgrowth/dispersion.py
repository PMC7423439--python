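"""Linear stability of the curvature-driven growth equation.

Linearizing ∂f/∂t = −f(1−f)·d·Δf − Δ²f about the uniform state f = f0 and
inserting plane waves f = f0 + f̂·exp(i k·x + σt) gives the dispersion relation

    σ(k) = f̃ d k² − k⁴,        f̃ = f0(1−f0),

an anti-diffusive destabilizing term regularized by hyper-diffusion.  σ changes
sign at k0 = (f̃ d)^(1/2) and peaks at k_max = (f̃ d / 2)^(1/2); the most
unstable wavelength λ_max = 2π/k_max sets the emergent wall spacing and
σ_max = σ(k_max) = f̃²d²/4 sets the natural time unit 1/σ_max of a growth run.

On a finite periodic domain of size L the smallest admissible wavenumber is
2π/L, so instability requires d above the marginal value d_c = (2π/L)²/f̃.

These closed forms are used for parameter selection, for normalizing
simulation time, and as the correctness oracle for the finite-difference
integrator (through their discrete-stencil counterparts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["sigma", "sigma_discrete", "stencil_eigenvalue", "summarize",
           "critical_d", "argmax_sigma_bruteforce", "DispersionSummary"]


def _f_tilde(f0: float) -> float:
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must lie strictly inside (0, 1)")
    return f0 * (1.0 - f0)


def sigma(k, d: float, f0: float = 0.5):
    """Continuum growth rate σ(k) = f̃ d k² − k⁴ of a plane wave of wavenumber k."""
    if d <= 0:
        raise ValueError("d must be strictly positive")
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("wavenumber k must be non-negative")
    ft = _f_tilde(f0)
    out = ft * d * k**2 - k**4
    return float(out) if out.ndim == 0 else out


def stencil_eigenvalue(k, h: float):
    """Eigenvalue k̃² of the 3-point second-difference stencil for mode cos(kx).

    k̃² = (2 − 2 cos(kh)) / h²; it approaches k² as kh → 0 and caps at 4/h².
    """
    if h <= 0:
        raise ValueError("spacing h must be positive")
    k = np.asarray(k, dtype=float)
    out = (2.0 - 2.0 * np.cos(k * h)) / h**2
    return float(out) if out.ndim == 0 else out


def sigma_discrete(k, d: float, f0: float = 0.5, h: float = 1.0):
    """Growth rate of a grid mode under the 7-point Laplacian / composed bi-Laplacian.

    Identical to :func:`sigma` with k² replaced by the stencil eigenvalue k̃²;
    this is the exact linear growth rate of the spatially discretized equation
    and the quantity a simulated single-mode perturbation must reproduce.
    """
    if d <= 0:
        raise ValueError("d must be strictly positive")
    kt2 = stencil_eigenvalue(k, h)
    return _f_tilde(f0) * d * kt2 - kt2**2


@dataclass(frozen=True)
class DispersionSummary:
    """Closed-form linear-analysis quantities for one value of d.

    ``sigma_max`` is σ(k_max) = f̃²d²/4 derived from the dispersion relation
    and is the value used for time normalization throughout.
    ``sigma_max_f0sq`` is the alternative convention f0²d²/4 sometimes quoted
    for this model; it exceeds the derived value by (f0/f̃)² — exactly 4 at
    f0 = 1/2 — and is carried under its own name so the two are never
    conflated.
    """

    d: float
    f0: float
    f_tilde: float
    k0: float
    k_max: float
    lambda0: float
    lambda_max: float
    sigma_max: float
    sigma_max_f0sq: float
    L: float | None = None
    d_c: float | None = None

    @property
    def timescale(self) -> float:
        """Natural time unit 1/σ_max of a growth run at this d."""
        return 1.0 / self.sigma_max

    def sigma(self, k):
        return sigma(k, self.d, self.f0)


def critical_d(L: float, f0: float = 0.5) -> float:
    """Marginal d for a periodic domain of size L: d_c = (2π/L)² / f̃."""
    if L <= 0:
        raise ValueError("domain size L must be positive")
    return (2.0 * math.pi / L) ** 2 / _f_tilde(f0)


def summarize(d: float, f0: float = 0.5, L: float | None = None) -> DispersionSummary:
    """All linear-analysis scalars for drive parameter d (and optionally domain L)."""
    if d <= 0:
        raise ValueError("d must be strictly positive")
    ft = _f_tilde(f0)
    k0 = math.sqrt(ft * d)
    k_max = math.sqrt(ft * d / 2.0)
    return DispersionSummary(
        d=float(d), f0=float(f0), f_tilde=ft,
        k0=k0, k_max=k_max,
        lambda0=2.0 * math.pi / k0, lambda_max=2.0 * math.pi / k_max,
        sigma_max=ft**2 * d**2 / 4.0,
        sigma_max_f0sq=f0**2 * d**2 / 4.0,
        L=L, d_c=None if L is None else critical_d(L, f0),
    )


def d_for_wavelength(lambda_max: float, f0: float = 0.5) -> float:
    """Drive parameter whose most unstable wavelength equals ``lambda_max``.

    Inverts k_max = (f̃ d / 2)^(1/2): d = 2 (2π/λ_max)² / f̃.  Convenient for
    choosing d so that the pattern is resolved by a prescribed number of grid
    cells.
    """
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    return 2.0 * (2.0 * math.pi / lambda_max) ** 2 / _f_tilde(f0)


def argmax_sigma_bruteforce(d: float, f0: float = 0.5,
                            k_grid: np.ndarray | None = None) -> tuple[float, float]:
    """Grid-search maximum of σ(k); independent check of the closed forms.

    By default scans (0, 2 k0] at step 1e-4·k0, fine enough to localize k_max
    to ~1e-4 relative accuracy.
    """
    if k_grid is None:
        k0 = math.sqrt(_f_tilde(f0) * d)
        k_grid = np.arange(1e-4, 2.0 * k0, 1e-4 * k0)
    s = sigma(k_grid, d, f0)
    i = int(np.argmax(s))
    return float(k_grid[i]), float(s[i])
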