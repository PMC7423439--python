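"""Scalar phase field on a 3D cubic grid, plus snapshot / image-stack I/O.

The phase field ``f`` is the single state object of the growth model: ``f > f0``
is interpreted as built material (nest wall), ``f < f0`` as empty space, and the
wall surface is the iso-surface ``f = f0``.  Micro-CT volumes of real nests are
grayscale stacks with the same reading (bright = wall), so simulated and scanned
volumes share this one container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

__all__ = ["BoundaryCondition", "ScalarField3D", "save_field", "load_field",
           "export_tiff_stack", "import_tiff_stack"]

_MIN_NODES = 8


@dataclass(frozen=True)
class BoundaryCondition:
    """Boundary handling for the cubic simulation grid.

    kind:
        ``"periodic"`` — all three axes wrap.
        ``"dirichlet_z"`` — x and y wrap; the z-min and z-max node planes are
        held at fixed values and a two-deep ghost halo beyond each plane is
        clamped to the same constant (the bi-Laplacian needs the second layer).
    """

    kind: str = "periodic"
    dirichlet_values: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("periodic", "dirichlet_z"):
            raise ValueError(f"unknown boundary condition kind {self.kind!r}")
        if self.kind == "dirichlet_z":
            if self.dirichlet_values is None:
                object.__setattr__(self, "dirichlet_values", (0.0, 0.0))
            vals = tuple(float(v) for v in self.dirichlet_values)
            if len(vals) != 2:
                raise ValueError("dirichlet_values must be (z_min_value, z_max_value)")
            object.__setattr__(self, "dirichlet_values", vals)
        elif self.dirichlet_values is not None:
            raise ValueError("dirichlet_values only apply to kind='dirichlet_z'")

    @property
    def periodic(self) -> bool:
        return self.kind == "periodic"


@dataclass
class ScalarField3D:
    """The phase field f sampled on an isotropic (nx, ny, nz) grid.

    Attributes
    ----------
    values : float64 array, shape (nx, ny, nz)
        Node values of f (dimensionless, nominally in [0, 1]).
    spacing : float
        Isotropic grid step h (dimensionless length).
    bc : BoundaryCondition
    time : float
        Current simulation time (dimensionless).
    """

    values: np.ndarray
    spacing: float = 1.0
    bc: BoundaryCondition = dc_field(default_factory=BoundaryCondition)
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if min(self.values.shape) < _MIN_NODES:
            raise ValueError(f"all axes need >= {_MIN_NODES} nodes, got {self.values.shape}")
        if not np.isscalar(self.spacing) or self.spacing <= 0:
            raise ValueError("spacing must be a positive scalar (isotropic grid)")
        self.spacing = float(self.spacing)
        if not isinstance(self.bc, BoundaryCondition):
            raise TypeError("bc must be a BoundaryCondition")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ScalarField3D":
        return replace(self, values=self.values.copy())

    def interface_voxel_count(self, level: float = 0.5, band: float = 0.25) -> int:
        """Number of nodes within ``band`` of the iso-level (diffuse interface)."""
        return int(np.count_nonzero(np.abs(self.values - level) < band))


# ---------------------------------------------------------------------------
# snapshot container: .npy payload + JSON sidecar with the metadata
# ---------------------------------------------------------------------------

def save_field(field: ScalarField3D, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a field as ``<path>.npy`` plus a ``<path>.json`` sidecar.

    The sidecar records shape, spacing, time and boundary conditions so a
    snapshot is self-describing; ``extra_meta`` (e.g. model parameter d, RNG
    seed) is merged in verbatim.
    """
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), field.values)
    meta = {
        "shape": list(field.shape),
        "spacing": field.spacing,
        "time": field.time,
        "bc": {"kind": field.bc.kind, "dirichlet_values": field.bc.dirichlet_values},
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npy")


def load_field(path: str | Path) -> ScalarField3D:
    """Load a field written by :func:`save_field`."""
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix("")
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    bc_meta = meta.get("bc", {"kind": "periodic", "dirichlet_values": None})
    dv = bc_meta.get("dirichlet_values")
    bc = BoundaryCondition(bc_meta.get("kind", "periodic"),
                           tuple(dv) if dv is not None else None)
    return ScalarField3D(values, spacing=float(meta.get("spacing", 1.0)), bc=bc,
                         time=float(meta.get("time", 0.0)))


def export_tiff_stack(field: ScalarField3D, path: str | Path) -> Path:
    """Write the volume as a multi-page float32 TIFF, one z-slice per page."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # CT convention: pages index z, each page is an (x, y) image
    tifffile.imwrite(path, np.moveaxis(field.values, 2, 0).astype(np.float32))
    return path


def import_tiff_stack(path: str | Path, spacing: float = 1.0,
                      normalize: bool = True) -> ScalarField3D:
    """Read a grayscale image stack (e.g. a micro-CT scan) as a phase field.

    Intensities are min-max rescaled to [0, 1] when ``normalize`` is set, so
    bright walls map near 1 and empty space near 0, matching the simulation
    convention.  The result carries periodic bc purely as a placeholder; real
    scans are not periodic and analyses must window them.
    """
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=np.float64)
    if stack.ndim == 2:
        raise ValueError("expected a 3D stack, got a single 2D image")
    values = np.moveaxis(stack, 0, 2)
    if normalize:
        lo, hi = values.min(), values.max()
        if hi <= lo:
            raise ValueError("constant image stack cannot be normalized")
        values = (values - lo) / (hi - lo)
    return ScalarField3D(values, spacing=spacing)
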