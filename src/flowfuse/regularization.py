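"""PC-MRI blurring operator and generalized-Tikhonov momentum solves.

A 3DFT Cartesian PC-MRI acquisition measures, per velocity component, a
blurred version of the true field: the point spread function of finite
k-space coverage is the separable sinc

    psi(x, y, z) = sinc(x/dx_m) * sinc(y/dy_m) * sinc(z/dz_m),

truncated to the box |x| <= 2*dx_m, |y| <= 2*dy_m, |z| <= 2*dz_m, where
(dx_m, dy_m, dz_m) are the MRI voxel spacings.  Sampling this kernel on the
CFD grid and normalizing each row to unit sum (so constant fields — DC — are
preserved, as velocity units require) yields the sparse M x N operator Gamma
mapping cell-centered CFD velocities to MRI voxels.  When the two grids
coincide the operator can be requested as the identity, which reproduces the
high-resolution phantom configuration.

During assimilation each momentum solve ``S x = f`` is replaced by the
minimizer of the generalized-Tikhonov objective

    J(x) = 1/2 ||S x - f||^2 + lambda/2 ||Gamma_eff x - m||^2,

whose closed form is the normal-equation solution
``(S'S + lambda Gamma'Gamma) x = S'f + lambda Gamma'm``.  Because momentum
unknowns are staggered face velocities while MRI voxels are cell-centered,
``Gamma_eff`` is Gamma composed with the face-to-center averaging map (and
the contribution of fixed boundary faces is moved into ``m``).  The solve is
performed iteratively on the stacked least-squares form — the normal matrix
is never formed densely.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import GridSpec, LumenMask
from .simpler import ActiveSets, BoundaryConditions, LinearSolveError, \
    MomentumSystem, solve_sparse

__all__ = [
    "PSFKernel",
    "RegularizationOperator",
    "build_psf",
    "build_gamma",
    "face_average_operator",
    "prepare_assimilation",
    "regularized_solve",
    "tikhonov_objective",
    "export_operator_mtx",
    "import_operator_mtx",
]


@dataclasses.dataclass
class PSFKernel:
    """Separable truncated-sinc kernel sampled on CFD-grid offsets.

    ``samples[a]`` holds the kernel values along axis ``a`` at offsets
    ``offsets[a]`` (meters, spaced by the CFD spacing, support
    ``|offset| <= 2 * mri_spacing[a]``).
    """

    offsets: tuple[np.ndarray, np.ndarray, np.ndarray]
    samples: tuple[np.ndarray, np.ndarray, np.ndarray]
    mri_spacing: tuple[float, float, float]
    cfd_spacing: tuple[float, float, float]

    def __call__(self, x, y, z):
        """Evaluate psi * B at arbitrary offsets (meters)."""
        out = np.ones(np.broadcast(x, y, z).shape)
        for coord, delta in zip((x, y, z), self.mri_spacing):
            c = np.asarray(coord, dtype=float)
            out = out * np.sinc(c / delta) * (np.abs(c) <= 2 * delta)
        return out


def build_psf(mri_spacing, cfd_spacing) -> PSFKernel:
    """Sample the truncated-sinc PSF on CFD-grid offsets, axis by axis."""
    mri_spacing = tuple(float(s) for s in mri_spacing)
    cfd_spacing = tuple(float(s) for s in cfd_spacing)
    for s in mri_spacing + cfd_spacing:
        if not s > 0:
            raise ValueError("spacings must be positive")
    offsets, samples = [], []
    for delta, h in zip(mri_spacing, cfd_spacing):
        kmax = int(np.floor(2 * delta / h + 1e-12))
        off = h * np.arange(-kmax, kmax + 1)
        offsets.append(off)
        samples.append(np.sinc(off / delta))
    return PSFKernel(tuple(offsets), tuple(samples), mri_spacing, cfd_spacing)


@dataclasses.dataclass
class RegularizationOperator:
    """Per-component blur/resampling operators and weights.

    ``gamma`` maps stacked cell-centered CFD values (N) to stacked MRI voxel
    values (M); rows sum to one.  ``lam`` are the nonnegative regularization
    weights (lambda_u, lambda_v, lambda_w).
    """

    gamma_u: sp.csr_matrix
    gamma_v: sp.csr_matrix
    gamma_w: sp.csr_matrix
    lam: tuple[float, float, float]
    M: int
    N: int

    def __post_init__(self):
        if any(l < 0 for l in self.lam):
            raise ValueError("lambda weights must be nonnegative")

    def gamma(self, axis: int) -> sp.csr_matrix:
        return (self.gamma_u, self.gamma_v, self.gamma_w)[axis]

    @classmethod
    def uniform(cls, gamma: sp.csr_matrix, lam) -> "RegularizationOperator":
        lam = tuple(float(l) for l in lam)
        return cls(gamma, gamma, gamma, lam, gamma.shape[0], gamma.shape[1])


def _axis_operator(c_mri: np.ndarray, c_cfd: np.ndarray, delta: float) -> sp.csr_matrix:
    """1-D blur/resample operator: rows = MRI positions, cols = CFD positions.

    Kernel sinc((x_cfd - x_mri)/delta) truncated at 2*delta; each row is
    normalized to unit sum (edge rows are renormalized over their truncated
    support).
    """
    diff = c_cfd[None, :] - c_mri[:, None]
    w = np.sinc(diff / delta) * (np.abs(diff) <= 2 * delta + 1e-12 * delta)
    sums = w.sum(axis=1)
    if np.any(np.abs(sums) < 1e-12):
        raise ValueError("empty overlap between MRI voxel and CFD grid")
    w /= sums[:, None]
    w[np.abs(w) < 1e-300] = 0.0
    return sp.csr_matrix(w)


def build_gamma(psf: PSFKernel, cfd_grid: GridSpec, mri_grid: GridSpec,
                identity: bool = False) -> sp.csr_matrix:
    """Build the sparse M x N operator from the separable kernel.

    With ``identity=True`` the grids must coincide and the exact identity is
    returned (the same-grid, high-resolution configuration).  Otherwise the
    operator is the Kronecker product of per-axis 1-D operators under the
    x-fastest stacking convention; it is symmetric when the grids coincide.
    """
    if identity:
        if cfd_grid.shape != mri_grid.shape or \
                not np.allclose(cfd_grid.spacing, mri_grid.spacing):
            raise ValueError("identity requested but grids differ")
        return sp.identity(cfd_grid.n_cells, format="csr")
    ops = []
    for ax in range(3):
        c_m = mri_grid.axis_centers(ax)
        c_c = cfd_grid.axis_centers(ax)
        lo, hi = c_c.min(), c_c.max()
        if c_m.min() < lo - 1e-9 or c_m.max() > hi + 1e-9:
            raise ValueError("MRI grid extends outside the CFD domain")
        ops.append(_axis_operator(c_m, c_c, psf.mri_spacing[ax]))
    # x fastest, then y, then z  ->  Gamma = Gz (x) Gy (x) Gx
    return sp.kron(ops[2], sp.kron(ops[1], ops[0], format="csr"),
                   format="csr")


def face_average_operator(grid: GridSpec, axis: int) -> sp.csr_matrix:
    """Sparse map from stacked face values to stacked cell-centered values.

    Row per cell (x-fastest order), 0.5 on each of the cell's two bounding
    faces of component ``axis``.
    """
    fshape = grid.face_shape(axis)
    n_faces = int(np.prod(fshape))
    n_cells = grid.n_cells
    # build in stacked (x-fastest) order explicitly
    ii, jj, kk = np.meshgrid(np.arange(grid.nx), np.arange(grid.ny),
                             np.arange(grid.nz), indexing="ij")
    ci = np.stack([ii.reshape(-1, order="F"),
                   jj.reshape(-1, order="F"),
                   kk.reshape(-1, order="F")], axis=1)
    lo = ci.copy()
    hi = ci.copy()
    hi[:, axis] += 1

    def face_flat(f):
        mult = np.array([1, fshape[0], fshape[0] * fshape[1]])
        return f @ mult

    rows = np.arange(n_cells)
    r = np.concatenate([rows, rows])
    c = np.concatenate([face_flat(lo), face_flat(hi)])
    v = np.full(2 * n_cells, 0.5)
    return sp.csr_matrix((v, (r, c)), shape=(n_cells, n_faces))


@dataclasses.dataclass
class AssimilationProblem:
    """Per-component effective operators/targets for the momentum solves.

    ``G[ax]`` maps the stacked *active-face* unknowns of one component to the
    retained measurement rows; ``m[ax]`` is the measurement vector with the
    fixed-face contribution subtracted; ``lam[ax]`` the weight.
    """

    G: list
    m: list
    lam: tuple[float, float, float]


def prepare_assimilation(
    reg: RegularizationOperator,
    measured: tuple[np.ndarray, np.ndarray, np.ndarray],
    grid: GridSpec,
    mask: LumenMask,
    sets: ActiveSets,
    bc: BoundaryConditions,
    row_masks=None,
) -> AssimilationProblem:
    """Compose Gamma with face averaging and fold in fixed faces.

    ``measured`` are the three cell-centered MRI component volumes on the
    MRI grid (stacked with x fastest).  ``row_masks`` optionally selects the
    measurement rows kept per component (boolean, length M); by default the
    rows of lumen FLUID voxels are kept — unmeasured voxels are simply
    omitted, which is also how partial-coverage protocols are expressed.
    """
    Gs, ms = [], []
    default_rows = mask.fluid.reshape(-1, order="F")
    for ax in range(3):
        lam = reg.lam[ax]
        if lam == 0:
            Gs.append(None)
            ms.append(None)
            continue
        gamma = reg.gamma(ax)
        rows = default_rows if row_masks is None else np.asarray(row_masks[ax])
        if rows.shape[0] != gamma.shape[0]:
            raise ValueError("row mask length does not match operator rows")
        R = gamma[rows]
        A = face_average_operator(grid, ax)
        GA = (R @ A).tocsc()
        act_flat = sets.active[ax].reshape(-1, order="F")
        G_act = GA[:, act_flat].tocsr()
        G_fix = GA[:, ~act_flat]
        fixed_vals = bc.fixed[ax].reshape(-1, order="F")[~act_flat]
        m_full = np.asarray(measured[ax]).reshape(-1, order="F")[rows]
        ms.append(m_full - G_fix @ fixed_vals)
        Gs.append(G_act)
    return AssimilationProblem(Gs, ms, reg.lam)


def tikhonov_objective(S, f, G, lam, m, x) -> float:
    r1 = S @ x - f
    r2 = G @ x - m
    return 0.5 * float(r1 @ r1) + 0.5 * lam * float(r2 @ r2)


def regularized_solve(sys: MomentumSystem | sp.spmatrix, gamma, lam: float,
                      m: np.ndarray, lin_tol: float = 1e-8,
                      x0: np.ndarray | None = None) -> np.ndarray:
    """Minimize ``1/2||Sx-f||^2 + lam/2 ||Gx-m||^2``.

    Accepts a :class:`MomentumSystem` or a bare matrix plus ``f`` packed in
    it.  ``lam = 0`` reduces exactly to the plain momentum solve.  The
    minimizer solves the stacked least-squares problem
    ``[S; sqrt(lam) G] x ~ [f; sqrt(lam) m]`` with LSMR (matrix-free normal
    equations); the optimality gradient ``S'(Sx-f) + lam G'(Gx-m)`` is
    verified and the iteration is restarted at tighter tolerance if needed.
    """
    if isinstance(sys, MomentumSystem):
        S, f = sys.S, sys.f
    else:
        raise TypeError("regularized_solve expects a MomentumSystem")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        return solve_sparse(S, f, lin_tol, x0)
    G = gamma.tocsr() if sp.issparse(gamma) else sp.csr_matrix(gamma)
    if G.shape[1] != S.shape[1] or G.shape[0] != len(m):
        raise ValueError("dimension mismatch between S, Gamma and m")

    sq = np.sqrt(lam)
    A = sp.vstack([S.tocsr(), sq * G], format="csr")
    b = np.concatenate([sys.f, sq * np.asarray(m, dtype=float)])

    ref = np.linalg.norm(S.T @ f)
    if ref == 0.0:
        ref = np.linalg.norm(lam * (G.T @ m)) or 1.0
    x = x0.copy() if x0 is not None else np.zeros(S.shape[1])
    atol = min(lin_tol, 1e-10)
    for _ in range(4):
        x = spla.lsmr(A, b, x0=x, atol=atol, btol=atol,
                      maxiter=20 * S.shape[1] + 1000)[0]
        grad = S.T @ (S @ x - f) + lam * (G.T @ (G @ x - m))
        if np.linalg.norm(grad) <= 1e-8 * ref:
            break
        atol *= 1e-3
        if atol < 1e-16:
            atol = 0.0
    grad_norm = np.linalg.norm(grad)
    if not np.isfinite(grad_norm) or grad_norm > 1e-6 * ref:
        raise LinearSolveError(
            f"regularized solve gradient norm {grad_norm:.3e} "
            f"exceeds 1e-6 * ||S'f + lam G'm|| = {1e-6 * ref:.3e}",
            grad_norm)
    return x


def export_operator_mtx(path, op: sp.spmatrix) -> None:
    """Write a sparse operator in MatrixMarket coordinate format."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(op))


def import_operator_mtx(path) -> sp.csr_matrix:
    from scipy.io import mmread

    return sp.csr_matrix(mmread(str(path)))
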