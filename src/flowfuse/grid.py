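"""Staggered Cartesian grids, lumen masks, and velocity/pressure fields.

The computational domain is a rectangular box of ``nx x ny x nz`` pressure
cells with uniform spacing ``(dx, dy, dz)``.  Pressure (and any cell-centered
quantity, including MRI-measured velocities) lives at cell centers; the three
velocity components live on the cell faces normal to their own axis (a MAC
grid, staggered by half a grid spacing, which prevents checkerboard pressure
modes):

* ``u`` on x-faces, shape ``(nx+1, ny, nz)``
* ``v`` on y-faces, shape ``(nx, ny+1, nz)``
* ``w`` on z-faces, shape ``(nx, ny, nz+1)``

All arrays are indexed ``[i, j, k]`` (0-based).  The linear (stacked-vector)
index convention is **x fastest, then y, then z**, i.e. cell ``(i, j, k)``
maps to ``i + nx*(j + ny*k)``; flattening/reshaping uses Fortran order.  SI
units throughout (meters, seconds, Pa); cm/s conversions happen only at I/O
boundaries.

The main through-flow axis is z: inlet and outlet cells sit on the ``k = 0``
and ``k = nz - 1`` boundary planes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = [
    "FLUID",
    "WALL",
    "INLET",
    "OUTLET",
    "GridSpec",
    "LumenMask",
    "StaggeredVelocityField",
    "FluidProperties",
    "build_grid",
    "stagger_to_centers",
    "centers_to_stagger",
    "divergence",
    "cell_centers",
    "face_centers",
    "load_mask_nifti",
    "save_mask_nifti",
    "load_velocity_nifti",
    "save_velocity_nifti",
    "save_vtk_structured_points",
]

# Cell labels (also the integer codes used in NIfTI mask volumes).
WALL = 0
FLUID = 1
INLET = 2
OUTLET = 3

_LABELS = (WALL, FLUID, INLET, OUTLET)


class ValidationError(ValueError):
    """Invalid geometry, mask, or field input."""


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Cartesian grid geometry.

    Parameters
    ----------
    nx, ny, nz : int
        Number of pressure cells along each axis (all >= 1).
    dx, dy, dz : float
        Cell spacing in meters (> 0).
    origin : tuple of float
        World position (m) of the center of cell ``(0, 0, 0)``.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for name in ("nx", "ny", "nz"):
            n = getattr(self, name)
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ValidationError(f"{name} must be a positive integer, got {n!r}")
        for name in ("dx", "dy", "dz"):
            d = getattr(self, name)
            if not d > 0:
                raise ValidationError(f"{name} must be > 0, got {d!r}")
        if len(self.origin) != 3:
            raise ValidationError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def n_cells(self) -> int:
        """Total pressure-cell count N = nx * ny * nz."""
        return self.nx * self.ny * self.nz

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the box (m) along each axis."""
        return (self.nx * self.dx, self.ny * self.dy, self.nz * self.dz)

    def face_shape(self, axis: int) -> tuple[int, int, int]:
        s = [self.nx, self.ny, self.nz]
        s[axis] += 1
        return tuple(s)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Cell-center coordinates along one axis (m)."""
        n = self.shape[axis]
        h = self.spacing[axis]
        return self.origin[axis] + h * np.arange(n)

    def flat_index(self, i, j, k):
        """Linear index of cell (i, j, k): x fastest, then y, then z."""
        return i + self.nx * (j + self.ny * k)


def build_grid(counts, spacings, origin=(0.0, 0.0, 0.0)) -> GridSpec:
    """Construct and validate a :class:`GridSpec`.

    ``counts`` and ``spacings`` are length-3 sequences; spacings in meters.
    """
    nx, ny, nz = (int(c) for c in counts)
    dx, dy, dz = (float(s) for s in spacings)
    return GridSpec(nx, ny, nz, dx, dy, dz, tuple(float(o) for o in origin))


def cell_centers(grid: GridSpec):
    """Meshgrid arrays (x, y, z), shape ``grid.shape``, of cell-center coords."""
    return np.meshgrid(
        grid.axis_centers(0), grid.axis_centers(1), grid.axis_centers(2),
        indexing="ij",
    )


def face_centers(grid: GridSpec, axis: int):
    """Meshgrid coord arrays for face centers of one velocity component."""
    coords = []
    for a in range(3):
        if a == axis:
            n = grid.shape[a] + 1
            c = grid.origin[a] - 0.5 * grid.spacing[a] + grid.spacing[a] * np.arange(n)
        else:
            c = grid.axis_centers(a)
        coords.append(c)
    return np.meshgrid(*coords, indexing="ij")


@dataclasses.dataclass
class LumenMask:
    """Per-cell labels: WALL(0), FLUID(1), INLET(2), OUTLET(3).

    Inlet and outlet cells must lie on the domain-boundary z-planes
    (``k = 0`` and ``k = nz - 1``).
    """

    labels: np.ndarray  # int array, shape grid.shape

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("mask labels must be a 3-D array")
        if not np.isin(self.labels, _LABELS).all():
            raise ValidationError("mask contains labels outside {0,1,2,3}")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def fluid(self) -> np.ndarray:
        return self.labels == FLUID

    @property
    def inlet(self) -> np.ndarray:
        return self.labels == INLET

    @property
    def outlet(self) -> np.ndarray:
        return self.labels == OUTLET

    @property
    def wall(self) -> np.ndarray:
        return self.labels == WALL

    @property
    def open(self) -> np.ndarray:
        """Cells carrying flow: FLUID, INLET or OUTLET."""
        return self.labels != WALL

    def validate(self, grid: GridSpec | None = None) -> None:
        """Check the structural invariants; raise ValidationError on failure."""
        if grid is not None and self.shape != grid.shape:
            raise ValidationError(
                f"mask shape {self.shape} does not match grid {grid.shape}")
        if not self.fluid.any():
            raise ValidationError("mask has no FLUID cell")
        nz = self.shape[2]
        io = self.inlet | self.outlet
        if io.any():
            kk = np.nonzero(io)[2]
            if not np.isin(kk, [0, nz - 1]).all():
                raise ValidationError(
                    "INLET/OUTLET cells must lie on boundary z-planes")
        # every FLUID cell 6-connected to at least one open cell
        op = self.open
        nbr = np.zeros(self.shape, dtype=bool)
        for ax in range(3):
            nbr |= _shift(op, ax, +1) | _shift(op, ax, -1)
        orphan = self.fluid & ~nbr
        if orphan.any():
            raise ValidationError(
                f"{orphan.sum()} FLUID cell(s) have no open 6-neighbor")


def _shift(a: np.ndarray, axis: int, step: int) -> np.ndarray:
    """Shift with zero/False fill (no wraparound)."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(0, -step)
        dst[axis] = slice(step, None)
    else:
        src[axis] = slice(-step, None)
        dst[axis] = slice(0, step)
    out[tuple(dst)] = a[tuple(src)]
    return out


@dataclasses.dataclass
class StaggeredVelocityField:
    """Velocity components on their staggered face grids (m/s)."""

    u: np.ndarray  # (nx+1, ny, nz)
    v: np.ndarray  # (nx, ny+1, nz)
    w: np.ndarray  # (nx, ny, nz+1)

    @classmethod
    def zeros(cls, grid: GridSpec) -> "StaggeredVelocityField":
        return cls(
            np.zeros(grid.face_shape(0)),
            np.zeros(grid.face_shape(1)),
            np.zeros(grid.face_shape(2)),
        )

    def component(self, axis: int) -> np.ndarray:
        return (self.u, self.v, self.w)[axis]

    def copy(self) -> "StaggeredVelocityField":
        return StaggeredVelocityField(self.u.copy(), self.v.copy(), self.w.copy())

    def check(self, grid: GridSpec) -> None:
        for ax, arr in enumerate((self.u, self.v, self.w)):
            if arr.shape != grid.face_shape(ax):
                raise ValidationError(
                    f"component {'uvw'[ax]} has shape {arr.shape}, "
                    f"expected {grid.face_shape(ax)}")
            if not np.isfinite(arr).all():
                raise ValidationError(f"component {'uvw'[ax]} contains non-finite values")


@dataclasses.dataclass(frozen=True)
class FluidProperties:
    """Constant Newtonian fluid: density rho (kg/m^3), viscosity mu (Pa s)."""

    rho: float
    mu: float

    def __post_init__(self):
        if not self.rho > 0:
            raise ValidationError(f"rho must be > 0, got {self.rho}")
        if not self.mu > 0:
            raise ValidationError(f"mu must be > 0, got {self.mu}")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (m^2/s)."""
        return self.mu / self.rho


def stagger_to_centers(field: StaggeredVelocityField, grid: GridSpec):
    """Average each component from its two bounding faces to cell centers.

    Returns three arrays of shape ``grid.shape``.  Exact for fields that are
    globally linear in the staggered coordinate.
    """
    field.check(grid)
    uc = 0.5 * (field.u[:-1, :, :] + field.u[1:, :, :])
    vc = 0.5 * (field.v[:, :-1, :] + field.v[:, 1:, :])
    wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:])
    return uc, vc, wc


def centers_to_stagger(uc, vc, wc, grid: GridSpec) -> StaggeredVelocityField:
    """Interpolate cell-centered components onto the staggered face grids.

    Interior faces take the mean of the two adjacent cell values; boundary
    faces copy the single adjacent cell (constant extrapolation).  Used to
    turn measured (cell-centered) velocity volumes into solver initial
    guesses and boundary profiles.
    """
    for arr in (uc, vc, wc):
        if np.shape(arr) != grid.shape:
            raise ValidationError("cell-centered component shape mismatch")
    f = StaggeredVelocityField.zeros(grid)
    f.u[1:-1, :, :] = 0.5 * (uc[:-1] + uc[1:])
    f.u[0, :, :] = uc[0]
    f.u[-1, :, :] = uc[-1]
    f.v[:, 1:-1, :] = 0.5 * (vc[:, :-1] + vc[:, 1:])
    f.v[:, 0, :] = vc[:, 0]
    f.v[:, -1, :] = vc[:, -1]
    f.w[:, :, 1:-1] = 0.5 * (wc[:, :, :-1] + wc[:, :, 1:])
    f.w[:, :, 0] = wc[:, :, 0]
    f.w[:, :, -1] = wc[:, :, -1]
    return f


def divergence(field: StaggeredVelocityField, grid: GridSpec) -> np.ndarray:
    """Discrete divergence per pressure cell (1/s), shape ``grid.shape``.

    ``(u_e - u_w)/dx + (v_n - v_s)/dy + (w_t - w_b)/dz`` — the natural
    finite-volume divergence on the MAC grid.
    """
    field.check(grid)
    return (
        (field.u[1:, :, :] - field.u[:-1, :, :]) / grid.dx
        + (field.v[:, 1:, :] - field.v[:, :-1, :]) / grid.dy
        + (field.w[:, :, 1:] - field.w[:, :, :-1]) / grid.dz
    )


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes (nibabel) and legacy-ASCII VTK for visualization
# ---------------------------------------------------------------------------

def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag([grid.dx * 1e3, grid.dy * 1e3, grid.dz * 1e3, 1.0])
    aff[:3, 3] = np.asarray(grid.origin) * 1e3  # NIfTI convention: mm
    return aff


def save_mask_nifti(path, mask: LumenMask, grid: GridSpec) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(grid))
    nib.save(img, str(path))


def load_mask_nifti(path) -> tuple[LumenMask, GridSpec]:
    """Read an integer-label mask volume; spacing (mm) from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int64)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3] * 1e-3
    grid = build_grid(labels.shape, [z * 1e-3 for z in zooms], origin)
    mask = LumenMask(labels)
    mask.validate(grid)
    return mask, grid


def save_velocity_nifti(path, components, grid: GridSpec, scale: float = 1.0) -> None:
    """Write three cell-centered components as a 4-D NIfTI (last axis u,v,w).

    ``scale`` converts from internal m/s to the stored unit (e.g. 100 for cm/s).
    """
    import nibabel as nib

    vol = np.stack([np.asarray(c) * scale for c in components], axis=-1)
    nib.save(nib.Nifti1Image(vol.astype(np.float64), _affine(grid)), str(path))


def load_velocity_nifti(path, scale: float = 1.0):
    """Read a 4-D velocity NIfTI; returns (components, grid).

    ``scale`` converts stored units to m/s (e.g. 0.01 for cm/s volumes).
    """
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4 or vol.shape[3] != 3:
        raise ValidationError("expected a 4-D volume with 3 components")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3] * 1e-3
    grid = build_grid(vol.shape[:3], [z * 1e-3 for z in zooms], origin)
    comps = tuple(vol[..., c] * scale for c in range(3))
    return comps, grid


def save_vtk_structured_points(path, grid: GridSpec, scalars=None, vectors=None) -> None:
    """Minimal legacy-ASCII VTK STRUCTURED_POINTS writer for visualization.

    ``scalars``/``vectors`` are dicts name -> array (cell-centered, shape
    ``grid.shape`` or ``grid.shape + (3,)``).  Data are written as point data
    on the cell-center lattice.
    """
    scalars = scalars or {}
    vectors = vectors or {}
    nx, ny, nz = grid.shape
    n = grid.n_cells
    lines = [
        "# vtk DataFile Version 3.0",
        "flowfuse export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {grid.dx} {grid.dy} {grid.dz}",
        f"POINT_DATA {n}",
    ]
    for name, arr in scalars.items():
        a = np.asarray(arr).reshape(n, order="F")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{x:.9g}" for x in a)
    for name, arr in vectors.items():
        a = np.asarray(arr).reshape(n, 3, order="F")
        lines.append(f"VECTORS {name} double")
        lines.extend(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in a)
    Path(path).write_text("\n".join(lines) + "\n")


def save_metadata_json(path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_metadata_json(path) -> dict:
    return json.loads(Path(path).read_text())
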