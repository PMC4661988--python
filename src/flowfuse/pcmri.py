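"""Synthetic ground-truth flows and PC-MRI measurement emulation.

The measurement chain emulated here is: true velocity field (staggered,
solver grid) -> cell centering -> truncated-sinc k-space blur -> resampling
onto the MRI grid -> per-component zero-mean Gaussian noise -> optional VENC
phase wrapping -> optional residual linear (eddy-current-like) velocity
offset.  Every stochastic stage is seeded, and all parameters are recorded
for provenance, so measurements are bit-reproducible.

Phantom geometries are voxelized analytic shapes: a straight circular pipe
(with adjustable profile bluntness, so a shear-thinning-like plug profile
can serve as ground truth that a Newtonian solver cannot reproduce exactly),
and a planar Y bifurcation standing in for a carotid geometry.  The paper's
two preprocessing fixes — unwrapping flagged aliased voxels by one VENC
period and removing a fitted linear offset over static tissue — are
implemented as measurement-to-measurement transforms.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grid import (
    FLUID,
    INLET,
    OUTLET,
    WALL,
    GridSpec,
    LumenMask,
    StaggeredVelocityField,
    cell_centers,
    face_centers,
    stagger_to_centers,
)
from .regularization import PSFKernel, build_gamma, build_psf

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "MRIMeasurement",
    "generate_poiseuille",
    "generate_bifurcation",
    "simulate_pcmri",
    "wrap_velocity",
    "unwrap_velocity",
    "remove_linear_offset",
]


@dataclasses.dataclass
class PhantomSpec:
    """Analytic phantom geometry.

    kind : "pipe", "bifurcation" or "cavity2d".
    radius : lumen radius (m); for the bifurcation, the parent radius.
    branch_radius : daughter-branch radius (m), bifurcation only.
    branch_span : lateral center-to-center separation of the daughter
        branches at the outlet plane (m).
    split_fraction : fraction of the z extent occupied by the parent vessel
        before the split.
    peak_velocity : peak inlet velocity w_max (m/s).
    profile_exponent : inlet/truth profile shape ``w = w_max (1 - (r/R)^q)``;
        q = 2 is Poiseuille, larger q a blunted (non-Newtonian-like) plug.
    """

    kind: str = "pipe"
    radius: float = 1.5e-3
    branch_radius: float = 1.1e-3
    branch_span: float = 3.2e-3
    split_fraction: float = 0.4
    peak_velocity: float = 0.4
    profile_exponent: float = 2.0

    def __post_init__(self):
        if self.kind not in ("pipe", "bifurcation", "cavity2d"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        for name in ("radius", "branch_radius", "branch_span",
                     "peak_velocity", "profile_exponent"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


@dataclasses.dataclass
class NoiseModel:
    """Measurement degradation parameters.

    sigma : per-component Gaussian noise standard deviation (m/s).
    seed : RNG seed (measurements are reproducible under the same seed).
    venc : velocity-encoding limit (m/s); velocities beyond +-venc alias.
    wrap : apply VENC phase wrapping.
    offset : optional per-component linear offsets, a mapping
        component -> (a, b, c, d) with units (m/s)/m for a, b, c and m/s
        for d, adding ``a x + b y + c z + d``.
    """

    sigma: float = 0.08
    seed: int = 0
    venc: float = 0.5
    wrap: bool = False
    offset: dict | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.venc > 0:
            raise ValueError("venc must be > 0")


@dataclasses.dataclass
class MRIMeasurement:
    """Cell-centered measured velocity volumes plus acquisition metadata."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    grid: GridSpec
    venc: float
    sigma: float = 0.0
    seed: int | None = None
    static_mask: np.ndarray | None = None

    def __post_init__(self):
        if not (self.u.shape == self.v.shape == self.w.shape):
            raise ValueError("measurement components must share one shape")

    def components(self):
        return (self.u, self.v, self.w)

    def component(self, axis: int):
        return (self.u, self.v, self.w)[axis]

    def stacked(self, axis: int) -> np.ndarray:
        """Component flattened with x fastest (the M x 1 measurement vector)."""
        return self.component(axis).reshape(-1, order="F")

    def copy(self) -> "MRIMeasurement":
        return dataclasses.replace(
            self, u=self.u.copy(), v=self.v.copy(), w=self.w.copy())


# ---------------------------------------------------------------------------
# Phantom geometries
# ---------------------------------------------------------------------------

def _radial_profile(r, R, w_max, q):
    prof = w_max * (1.0 - (np.minimum(r, R) / R) ** q)
    return np.where(r < R, prof, 0.0)


def generate_poiseuille(spec: PhantomSpec, grid: GridSpec):
    """Straight circular pipe along z with an analytic axial profile.

    Returns ``(mask, truth)``: the lumen mask (INLET/OUTLET on the boundary
    z-planes) and the staggered ground-truth field with
    ``w(r) = w_max (1 - (r/R)^q)`` inside radius R and u = v = 0.
    """
    if spec.kind != "pipe":
        raise ValueError("generate_poiseuille requires a 'pipe' spec")
    R = spec.radius
    cx = grid.origin[0] + 0.5 * (grid.nx - 1) * grid.dx
    cy = grid.origin[1] + 0.5 * (grid.ny - 1) * grid.dy
    if R > 0.5 * min(grid.extent[0], grid.extent[1]):
        raise ValueError("pipe radius exceeds the grid cross-section")

    x, y, _ = cell_centers(grid)
    r_cells = np.hypot(x - cx, y - cy)
    lumen = r_cells < R
    labels = np.where(lumen, FLUID, WALL)
    labels[:, :, 0] = np.where(lumen[:, :, 0], INLET, WALL)
    labels[:, :, -1] = np.where(lumen[:, :, -1], OUTLET, WALL)
    mask = LumenMask(labels)
    mask.validate(grid)

    truth = StaggeredVelocityField.zeros(grid)
    xf, yf, _ = face_centers(grid, 2)
    r_faces = np.hypot(xf - cx, yf - cy)
    truth.w[...] = _radial_profile(r_faces, R, spec.peak_velocity,
                                   spec.profile_exponent)
    # zero any face touching a wall cell
    open_cells = mask.open
    wall_adj = np.ones_like(truth.w, dtype=bool)
    wall_adj[:, :, :-1] &= ~open_cells
    wall_adj[:, :, 1:] &= ~open_cells
    truth.w[wall_adj] = 0.0
    return mask, truth


def generate_bifurcation(spec: PhantomSpec, grid: GridSpec):
    """Voxelized planar Y geometry: one parent tube splitting into two.

    The parent runs along z from the inlet plane; past the split the two
    daughter lumens translate apart in x (circular cross-sections of radius
    ``branch_radius``) until their centers are ``branch_span`` apart at the
    outlet plane.  Returns ``(mask, truth)`` where the truth field carries
    the parabolic inlet profile on the inlet faces (the interior is zero —
    the flow there is the solver's job).
    """
    if spec.kind != "bifurcation":
        raise ValueError("generate_bifurcation requires a 'bifurcation' spec")
    cx = grid.origin[0] + 0.5 * (grid.nx - 1) * grid.dx
    cy = grid.origin[1] + 0.5 * (grid.ny - 1) * grid.dy
    Lz = grid.extent[2]
    z0 = grid.origin[2] - 0.5 * grid.dz
    z_split = z0 + spec.split_fraction * Lz
    half_span = 0.5 * spec.branch_span
    if half_span + spec.branch_radius > 0.5 * grid.extent[0]:
        raise ValueError("branches leave the domain in x")

    x, y, z = cell_centers(grid)
    t = np.clip((z - z_split) / (z0 + Lz - z_split), 0.0, 1.0)
    off = half_span * t
    in_parent = (np.hypot(x - cx, y - cy) < spec.radius) & (z <= z_split)
    in_left = np.hypot(x - (cx - off), y - cy) < spec.branch_radius
    in_right = np.hypot(x - (cx + off), y - cy) < spec.branch_radius
    lumen = in_parent | ((z > z_split) & (in_left | in_right))
    # keep branches open through the split plane
    lumen |= (z <= z_split) & (np.hypot(x - cx, y - cy) < spec.radius)

    labels = np.where(lumen, FLUID, WALL)
    labels[:, :, 0] = np.where(lumen[:, :, 0], INLET, WALL)
    labels[:, :, -1] = np.where(lumen[:, :, -1], OUTLET, WALL)
    mask = LumenMask(labels)
    mask.validate(grid)

    truth = StaggeredVelocityField.zeros(grid)
    xf, yf, _ = face_centers(grid, 2)
    rf = np.hypot(xf - cx, yf - cy)
    prof = _radial_profile(rf[:, :, 0], spec.radius, spec.peak_velocity,
                           spec.profile_exponent)
    truth.w[:, :, 0] = np.where(mask.inlet[:, :, 0], prof, 0.0)
    truth.w[:, :, 1] = truth.w[:, :, 0]
    return mask, truth


def lumen_connected_components(mask: LumenMask) -> int:
    """Number of 6-connected components of the open (non-wall) region."""
    from scipy import ndimage

    _, n = ndimage.label(mask.open,
                         structure=ndimage.generate_binary_structure(3, 1))
    return int(n)


# ---------------------------------------------------------------------------
# Measurement simulation and preprocessing
# ---------------------------------------------------------------------------

def wrap_velocity(values: np.ndarray, venc: float) -> np.ndarray:
    """VENC aliasing: map velocities into [-venc, venc)."""
    return np.mod(values + venc, 2.0 * venc) - venc


def simulate_pcmri(
    truth: StaggeredVelocityField,
    cfd_grid: GridSpec,
    mri_grid: GridSpec | None = None,
    psf: PSFKernel | None = None,
    noise: NoiseModel | None = None,
    lumen: LumenMask | None = None,
) -> MRIMeasurement:
    """Emulate a PC-MRI acquisition of a known staggered velocity field.

    With ``mri_grid``/``psf`` omitted the degenerate same-grid identity
    pipeline is used (no blur, no resampling).  Noise draws are independent
    per component and voxel; the sub-generator for each component is derived
    from ``noise.seed`` so components are independent but reproducible.
    """
    noise = noise or NoiseModel(sigma=0.0)
    centered = stagger_to_centers(truth, cfd_grid)
    if mri_grid is None or (psf is None and mri_grid.shape == cfd_grid.shape
                            and np.allclose(mri_grid.spacing, cfd_grid.spacing)):
        mri_grid = mri_grid or cfd_grid
        measured = [c.copy() for c in centered]
    else:
        if psf is None:
            psf = build_psf(mri_grid.spacing, cfd_grid.spacing)
        gamma = build_gamma(psf, cfd_grid, mri_grid)
        measured = [
            (gamma @ c.reshape(-1, order="F")).reshape(mri_grid.shape, order="F")
            for c in centered
        ]

    rng = np.random.default_rng(noise.seed)
    streams = rng.spawn(3)
    out = []
    for ax, comp in enumerate(measured):
        m = comp.astype(float)
        if noise.sigma > 0:
            m = m + streams[ax].normal(0.0, noise.sigma, size=m.shape)
        if noise.offset:
            coeffs = noise.offset.get("uvw"[ax])
            if coeffs is not None:
                a, b, c, d = coeffs
                x, y, z = cell_centers(mri_grid)
                m = m + a * x + b * y + c * z + d
        if noise.wrap:
            m = wrap_velocity(m, noise.venc)
        out.append(m)

    static = None
    if lumen is not None and mri_grid.shape == cfd_grid.shape:
        static = ~lumen.open
    return MRIMeasurement(out[0], out[1], out[2], mri_grid,
                          venc=noise.venc, sigma=noise.sigma,
                          seed=noise.seed, static_mask=static)


def unwrap_velocity(meas: MRIMeasurement, flagged, components=("u", "v", "w"),
                    direction: int = +1) -> MRIMeasurement:
    """Add ``direction * 2 * VENC`` to the flagged voxels of the given
    components (one aliasing period, the 2*pi phase fix).

    ``flagged`` is a boolean volume or an index tuple; idempotent on
    unflagged voxels.  Inverse of a single wrap for |v| < 3*VENC.
    """
    out = meas.copy()
    flag = np.asarray(flagged)
    if flag.dtype == bool:
        if flag.shape != meas.u.shape:
            raise ValueError("flag volume shape mismatch")
        sel = flag
    else:
        idx = tuple(np.asarray(flagged).T) if np.ndim(flagged) == 2 else flagged
        sel = np.zeros(meas.u.shape, dtype=bool)
        try:
            sel[idx] = True
        except IndexError as exc:
            raise ValueError("flagged voxel index out of range") from exc
    shift = direction * 2.0 * meas.venc
    for name in components:
        comp = getattr(out, name)
        comp[sel] += shift
    return out


def remove_linear_offset(meas: MRIMeasurement,
                         static_mask: np.ndarray | None = None):
    """Fit and subtract a linear plane ``a x + b y + c z + d`` per component.

    The least-squares fit runs over the static-tissue region (default: the
    measurement's own static mask); the plane is subtracted everywhere.
    Returns ``(corrected, coefficients)`` where coefficients maps component
    name to the fitted (a, b, c, d).
    """
    mask = static_mask if static_mask is not None else meas.static_mask
    if mask is None:
        raise ValueError("no static-tissue mask available")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != meas.u.shape:
        raise ValueError("static mask shape mismatch")
    pts = mask.sum()
    if pts < 4:
        raise ValueError("static region must contain at least 4 voxels")
    x, y, z = cell_centers(meas.grid)
    A = np.column_stack([x[mask], y[mask], z[mask], np.ones(pts)])
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("static region is degenerate (coplanar voxels)")
    out = meas.copy()
    coeffs = {}
    for name in ("u", "v", "w"):
        comp = getattr(out, name)
        sol, *_ = np.linalg.lstsq(A, comp[mask], rcond=None)
        a, b, c, d = sol
        comp -= a * x + b * y + c * z + d
        coeffs[name] = (float(a), float(b), float(c), float(d))
    return out, coeffs
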