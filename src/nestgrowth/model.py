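"""Curvature-driven phase-field growth model.

The nest is a scalar phase field f on a cubic grid evolving under

    ∂f/∂t = −f^α (1−f)^β · d · Δf − Δ²f,

the simplified form in which the mean curvature of the local iso-surface,
∇·n̂ with n̂ = ∇f/|∇f|, is approximated by Δf (valid where |∇f| is roughly
constant across the diffuse interface; d is then an effective drive
parameter).  The anti-diffusive first term deposits material where the wall
surface is convex toward the empty space, the kernel f^α(1−f)^β confines
growth to the interface region (no deposition in empty space, no remodelling
deep inside walls), and the bi-Laplacian smooths away features below the
cut-off wavelength λ0.

Integration is first-order explicit Euler on a 7-point Laplacian stencil, with
the bi-Laplacian formed by composing the same stencil.  Boundary conditions
are triply periodic, or periodic laterally with fixed-value (Dirichlet) planes
at z-min/z-max.  Initial conditions: uniform white noise about f0, or a frozen
"nest-like" seed (noisy half-sphere, or a patch copied from a matured run)
whose nodes never evolve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .dispersion import summarize
from .field import BoundaryCondition, ScalarField3D

__all__ = [
    "GrowthConfig", "IntegrationError", "HalfSphereSeed", "VolumePatchSeed",
    "stable_dt", "laplacian", "bilaplacian", "curvature_divergence",
    "init_white_noise", "init_seeded", "step", "run", "RunResult",
]

logger = logging.getLogger(__name__)

_OVERSHOOT_LO, _OVERSHOOT_HI = -0.05, 1.05


class IntegrationError(RuntimeError):
    """Raised when the explicit Euler integration produces non-finite values."""


def stable_dt(d: float, spacing: float = 1.0, f0: float = 0.5,
              safety: float = 0.25) -> float:
    """Largest safe explicit-Euler step for the linearized operator.

    On a 3D grid the second-difference stencil eigenvalues reach K2 = 12/h²
    (Laplacian) and K4 = K2² (composed bi-Laplacian), so the most negative
    linear rate is bounded by f̃·d·K2 + K4 and explicit Euler is stable for
    dt ≤ 2/(f̃·d·K2 + K4).  A safety factor (default 0.25) absorbs the
    nonlinear kernel exceeding its uniform-state value during transients.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if d < 0:
        raise ValueError("d must be non-negative")
    ft = f0 * (1.0 - f0)
    k2 = 12.0 / spacing**2
    k4 = k2 * k2
    return safety * 2.0 / (ft * d * k2 + k4)


@dataclass(frozen=True)
class GrowthConfig:
    """All model and numerics parameters of a growth run.

    Parameters
    ----------
    d : float
        Curvature-drive coefficient (> 0).  Sets the most unstable wavelength
        λ_max = 2π/√(f̃d/2) and the growth timescale 1/σ_max.
    alpha, beta : float
        Kernel exponents of f^α(1−f)^β; both 1 by default, which puts the
        kernel maximum (and the wall surface) at f0 = 1/2.
    f0 : float
        Iso-surface level separating material from empty space.
    spacing : float
        Grid step h.  The default drive parameters are usually chosen so that
        λ_max spans at least ~12 cells.
    dt : float or None
        Euler time step; None selects :func:`stable_dt`.  A dt above the
        stability bound is rejected at construction.
    frozen_threshold : float in (0, 1] or None
        Nodes whose *initial* value exceeds this never evolve (seed support);
        None disables freezing.
    dirichlet_values : (float, float) or None
        Fixed f at the z-min / z-max node planes; None means triply periodic.
    rng_seed : int
        Seed for every stochastic initial condition.
    noise_amplitude : float
        Half-width of the uniform white noise about f0 (initial condition).
    clamp : bool
        Clamp f to [0, 1] after each step.  Off by default: the kernel
        self-damps near 0 and 1, and mild overshoot only triggers a warning.
    """

    d: float
    alpha: float = 1.0
    beta: float = 1.0
    f0: float = 0.5
    spacing: float = 1.0
    dt: float | None = None
    frozen_threshold: float | None = 0.9
    dirichlet_values: tuple[float, float] | None = None
    rng_seed: int = 0
    noise_amplitude: float = 0.1
    clamp: bool = False

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be strictly positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("kernel exponents alpha, beta must be positive")
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("f0 must lie in (0, 1)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")
        if self.frozen_threshold is not None and not 0.0 < self.frozen_threshold <= 1.0:
            raise ValueError("frozen_threshold must be in (0, 1] or None")
        bound = stable_dt(self.d, self.spacing, self.f0)
        if self.dt is None:
            object.__setattr__(self, "dt", bound)
        elif not 0.0 < self.dt <= bound:
            raise ValueError(
                f"dt={self.dt:g} violates the explicit-Euler stability bound "
                f"{bound:g} for d={self.d:g}, h={self.spacing:g}")

    @property
    def bc(self) -> BoundaryCondition:
        if self.dirichlet_values is None:
            return BoundaryCondition("periodic")
        return BoundaryCondition("dirichlet_z", tuple(self.dirichlet_values))

    @property
    def timescale(self) -> float:
        """Natural time unit 1/σ_max of the linear instability at this d."""
        return summarize(self.d, self.f0).timescale


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def _lap(values: np.ndarray, spacing: float, bc: BoundaryCondition,
         ghost: tuple[float, float] | None, out: np.ndarray) -> np.ndarray:
    inv_h2 = 1.0 / spacing**2
    if bc.periodic:
        _kernels.lap_periodic(values, inv_h2, out)
    else:
        lo, hi = ghost if ghost is not None else bc.dirichlet_values
        _kernels.lap_dirichlet_z(values, inv_h2, float(lo), float(hi), out)
    return out


def laplacian(field: ScalarField3D) -> np.ndarray:
    """7-point second-order central-difference Laplacian, scaled by 1/h².

    Periodic axes wrap; with fixed-value z planes the ghost layers are clamped
    to the boundary constants.
    """
    values = np.ascontiguousarray(field.values)
    return _lap(values, field.spacing, field.bc, None, np.empty_like(values))


def bilaplacian(field: ScalarField3D) -> np.ndarray:
    """Bi-Laplacian Δ²f as the Laplacian stencil applied twice.

    The same ghost policy is used for both passes: with Dirichlet planes the
    field is clamped to the boundary constant beyond the z faces, so the first
    pass returns exactly zero on the ghost layers and the second pass uses
    zero ghosts.
    """
    values = np.ascontiguousarray(field.values)
    lap1 = _lap(values, field.spacing, field.bc, None, np.empty_like(values))
    return _lap(lap1, field.spacing, field.bc, (0.0, 0.0), np.empty_like(values))


def curvature_divergence(field: ScalarField3D, grad_floor: float = 1e-12) -> np.ndarray:
    """Diagnostic: the full iso-surface mean-curvature operator ∇·(∇f/|∇f|).

    Provided for comparing the Δf approximation against the exact curvature
    term; it is *not* integrated in time.  |∇f| is floored at ``grad_floor``
    to keep the normal field defined where f is flat.  Central differences,
    with one-sided differences at non-periodic z faces.
    """
    h = field.spacing
    f = field.values
    if field.bc.periodic:
        def grad(a):
            return [(np.roll(a, -1, ax) - np.roll(a, 1, ax)) / (2 * h) for ax in range(3)]
    else:
        def grad(a):
            return list(np.gradient(a, h))
    gx, gy, gz = grad(f)
    norm = np.sqrt(gx * gx + gy * gy + gz * gz)
    norm = np.maximum(norm, grad_floor)
    nxd, nyd, nzd = gx / norm, gy / norm, gz / norm
    div = grad(nxd)[0] + grad(nyd)[1] + grad(nzd)[2]
    return div


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _apply_dirichlet_planes(values: np.ndarray, bc: BoundaryCondition) -> None:
    if not bc.periodic:
        lo, hi = bc.dirichlet_values
        values[:, :, 0] = lo
        values[:, :, -1] = hi


def init_white_noise(shape: tuple[int, int, int], cfg: GrowthConfig) -> ScalarField3D:
    """Uniform i.i.d. white noise about f0: f = f0 + a·U, U ~ U(−1, 1) per node.

    Reproducible from ``cfg.rng_seed``.  Amplitudes that would push f outside
    (0, 1) are rejected.
    """
    a = cfg.noise_amplitude
    if a >= min(cfg.f0, 1.0 - cfg.f0):
        raise ValueError(f"noise_amplitude {a:g} pushes f outside (0, 1) around f0={cfg.f0:g}")
    rng = np.random.default_rng(cfg.rng_seed)
    values = cfg.f0 + a * rng.uniform(-1.0, 1.0, size=shape)
    bc = cfg.bc
    _apply_dirichlet_planes(values, bc)
    return ScalarField3D(values, spacing=cfg.spacing, bc=bc, time=0.0)


@dataclass(frozen=True)
class HalfSphereSeed:
    """Solid half-sphere resting on the z-min floor, optional noisy surface.

    ``center`` is the (x, y) node index of the axis; None centres it in the
    domain.  ``surface_noise_amplitude`` perturbs the radius threshold per
    node by a uniform amount in length units, roughening the seed surface.
    """

    radius: float
    center: tuple[float, float] | None = None
    surface_noise_amplitude: float = 0.0


@dataclass(frozen=True)
class VolumePatchSeed:
    """A stored field (e.g. part of a matured run) pasted at ``offset``, rest 0."""

    values: np.ndarray
    offset: tuple[int, int, int] = (0, 0, 0)


def init_seeded(shape: tuple[int, int, int], cfg: GrowthConfig,
                seed_spec: HalfSphereSeed | VolumePatchSeed,
                ) -> tuple[ScalarField3D, np.ndarray]:
    """Seeded initial condition: f = 1 inside the seed, 0 elsewhere.

    Returns the field together with the frozen-node mask
    ``initial f > cfg.frozen_threshold`` (all-False when freezing is
    disabled); pass the mask to :func:`step`/:func:`run` to keep the seed
    bit-invariant.  Frozen seed nodes take precedence over Dirichlet planes
    they touch (the seed is the physical support the nest grows from).
    """
    nx, ny, nz = shape
    h = cfg.spacing
    values = np.zeros(shape, dtype=np.float64)
    bc = cfg.bc
    _apply_dirichlet_planes(values, bc)

    if isinstance(seed_spec, HalfSphereSeed):
        R = float(seed_spec.radius)
        if R < 0:
            raise ValueError("radius must be non-negative")
        cx, cy = seed_spec.center if seed_spec.center is not None else ((nx - 1) / 2.0, (ny - 1) / 2.0)
        a = seed_spec.surface_noise_amplitude
        if R + a > min(cx, nx - 1 - cx, cy, ny - 1 - cy, nz - 1) * h and R > 0:
            raise ValueError("half-sphere seed does not fit inside the domain")
        if R > 0:
            x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
            r = h * np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + z.astype(float) ** 2)
            thresh = R
            if a > 0:
                rng = np.random.default_rng(cfg.rng_seed)
                thresh = R + a * rng.uniform(-1.0, 1.0, size=shape)
            values[r <= thresh] = 1.0
    elif isinstance(seed_spec, VolumePatchSeed):
        patch = np.asarray(seed_spec.values, dtype=np.float64)
        ox, oy, oz = seed_spec.offset
        if any(o < 0 for o in seed_spec.offset) or \
                ox + patch.shape[0] > nx or oy + patch.shape[1] > ny or oz + patch.shape[2] > nz:
            raise ValueError("volume patch does not fit inside the domain")
        values[ox:ox + patch.shape[0], oy:oy + patch.shape[1], oz:oz + patch.shape[2]] = patch
    else:
        raise TypeError("seed_spec must be a HalfSphereSeed or VolumePatchSeed")

    if cfg.frozen_threshold is not None:
        frozen = values > cfg.frozen_threshold
    else:
        frozen = np.zeros(shape, dtype=bool)
    return ScalarField3D(values, spacing=h, bc=bc, time=0.0), frozen


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

def _active_mask(shape, bc: BoundaryCondition, frozen_mask: np.ndarray | None) -> np.ndarray:
    active = np.ones(shape, dtype=np.bool_)
    if frozen_mask is not None:
        if frozen_mask.shape != tuple(shape):
            raise ValueError("frozen_mask shape does not match the field")
        active &= ~frozen_mask
    if not bc.periodic:
        active[:, :, 0] = False
        active[:, :, -1] = False
    return active


def step(field: ScalarField3D, cfg: GrowthConfig,
         frozen_mask: np.ndarray | None = None) -> ScalarField3D:
    """One explicit Euler step; returns a new field, input left untouched.

    Frozen nodes and fixed-value planes are skipped; a NaN/Inf appearing in
    the update raises :class:`IntegrationError`.
    """
    out = field.copy()
    _step_inplace(out, cfg, _active_mask(field.shape, field.bc, frozen_mask),
                  np.empty_like(out.values), np.empty_like(out.values))
    if not np.all(np.isfinite(out.values)):
        raise IntegrationError("non-finite values after 1 step (unstable configuration)")
    return out


def _step_inplace(field: ScalarField3D, cfg: GrowthConfig, active: np.ndarray,
                  buf1: np.ndarray, buf2: np.ndarray) -> None:
    values = field.values
    _lap(values, field.spacing, field.bc, None, buf1)
    _lap(buf1, field.spacing, field.bc, (0.0, 0.0), buf2)
    _kernels.euler_update(values, buf1, buf2, active, cfg.dt, cfg.d,
                          float(cfg.alpha), float(cfg.beta))
    if cfg.clamp:
        np.clip(values, 0.0, 1.0, out=values)
    field.time += cfg.dt


@dataclass
class RunResult:
    """Snapshots plus a per-snapshot log of a growth run."""

    snapshots: list[ScalarField3D]
    log: list[dict] = dc_field(default_factory=list)

    @property
    def final(self) -> ScalarField3D:
        return self.snapshots[-1]


def run(field: ScalarField3D, cfg: GrowthConfig,
        frozen_mask: np.ndarray | None = None, t_end: float = 0.0,
        snapshot_every: float | None = None, check_every: int = 200) -> RunResult:
    """Integrate until ``time >= t_end``, collecting snapshots.

    ``snapshot_every`` is the snapshot interval in simulation time (None keeps
    only the initial and final states).  The log records, per snapshot, the
    time both in simulation units and in linear-growth timescales 1/σ_max,
    the min/max of f, and the interface voxel count (|f − f0| < 0.25).
    Finiteness is checked every ``check_every`` steps; failure raises
    :class:`IntegrationError` naming the step count.
    """
    if t_end < field.time:
        raise ValueError("t_end must be >= current field time")
    sigma_max = summarize(cfg.d, cfg.f0).sigma_max
    current = field.copy()
    active = _active_mask(current.shape, current.bc, frozen_mask)
    buf1 = np.empty_like(current.values)
    buf2 = np.empty_like(current.values)

    result = RunResult(snapshots=[])
    warned_overshoot = False

    def _record():
        nonlocal warned_overshoot
        snap = current.copy()
        result.snapshots.append(snap)
        fmin, fmax = float(snap.values.min()), float(snap.values.max())
        if not warned_overshoot and (fmin < _OVERSHOOT_LO or fmax > _OVERSHOOT_HI):
            logger.warning("field overshoots [%g, %g]: min=%g max=%g at t=%g",
                           _OVERSHOOT_LO, _OVERSHOOT_HI, fmin, fmax, snap.time)
            warned_overshoot = True
        result.log.append({
            "time": snap.time,
            "timescales": snap.time * sigma_max,
            "f_min": fmin,
            "f_max": fmax,
            "interface_voxels": snap.interface_voxel_count(cfg.f0),
        })

    _record()
    if t_end == field.time:
        return result

    next_snap = (field.time + snapshot_every) if snapshot_every else math.inf
    n_steps = 0
    eps = 0.5 * cfg.dt
    while current.time < t_end - eps:
        _step_inplace(current, cfg, active, buf1, buf2)
        n_steps += 1
        if n_steps % check_every == 0 and not np.all(np.isfinite(current.values)):
            raise IntegrationError(f"non-finite values after {n_steps} steps")
        if current.time >= next_snap - eps and current.time < t_end - eps:
            _record()
            next_snap += snapshot_every
    if not np.all(np.isfinite(current.values)):
        raise IntegrationError(f"non-finite values after {n_steps} steps")
    _record()
    return result
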