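"""Finite-volume SIMPLER solver for steady incompressible flow.

Discretization
--------------
Momentum is discretized with the finite-volume power-law convection–diffusion
scheme on the staggered (MAC) grid, giving for each velocity component a
sparse linear system ``S x = f`` with at most 7 nonzeros per row
(hepta-diagonal under the x-fastest linear index order).  A pseudo-transient
term ``rho*dV/dt`` is added to the diagonal, so marching the outer loop in
pseudo-time ``dt`` until the update rate ``||v(t+dt) - v(t)|| / dt`` falls
below ``eps`` yields the steady state.

Each pseudo-time step is converged by SIMPLER (Semi-Implicit Method for
Pressure-Linked Equations, Revised) inner iterations:

1. pseudo-velocities from the momentum coefficients (no pressure term);
2. pressure equation (a discrete Poisson problem) from the pseudo-velocity
   mass imbalance;
3. momentum solves for the starred velocities using that pressure — these are
   the solves that become generalized-Tikhonov minimizations when MRI
   assimilation is active (see :mod:`flowfuse.regularization`);
4. pressure-correction equation from the starred-velocity mass imbalance;
5. velocity correction, which restores discrete continuity.

The inner residual reported is the max-norm divergence of the starred field
(the mass imbalance the correction removes); it vanishes as the nonlinear
iteration converges.  The corrected field satisfies discrete continuity to
linear-solver accuracy at every iteration.

Geometry is an immersed ("masked box") description: the rectangular grid
carries a lumen mask, velocity unknowns are the faces between two FLUID
cells, every other face is fixed (0 on walls, measured profiles on the
inlet/outlet z-planes), and WALL-interior cells are excluded from the
systems.  Tangential no-slip at wall cells is imposed at the half-cell wall
plane (first order).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import (
    FLUID,
    FluidProperties,
    GridSpec,
    LumenMask,
    StaggeredVelocityField,
    divergence,
)

__all__ = [
    "SolverConfig",
    "SolverResult",
    "MomentumSystem",
    "BoundaryConditions",
    "ActiveSets",
    "LinearSolveError",
    "bc_from_profiles",
    "assemble_momentum",
    "solve_sparse",
    "solve_pressure",
    "simpler_iteration",
    "run_steady_state",
]


class LinearSolveError(RuntimeError):
    """Iterative linear solve failed to reach the requested tolerance."""

    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


@dataclasses.dataclass
class SolverConfig:
    """Numerical parameters of the pseudo-transient SIMPLER solver.

    dt : pseudo-time step (s).  Larger steps converge in fewer outer
        iterations; the momentum diagonal carries ``rho*dV/dt``.
    eps : steady-state tolerance on the update rate ``||dv||_rms / dt``
        (m/s^2).
    div_tol : inner continuity tolerance on the pre-correction mass
        imbalance, max-norm divergence (1/s).
    max_outer, max_inner : iteration caps (outer pseudo-time steps, inner
        SIMPLER iterations per step).
    lin_tol : relative residual tolerance of the momentum Krylov solves.
    relax_u, relax_p : under-relaxation factors in (0, 1].
    """

    dt: float = 1e-3
    eps: float = 1e-2
    div_tol: float = 1e-3
    max_outer: int = 2000
    max_inner: int = 10
    lin_tol: float = 1e-8
    relax_u: float = 0.7
    relax_p: float = 1.0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        for name in ("eps", "div_tol", "lin_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("relax_u", "relax_p"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclasses.dataclass
class MomentumSystem:
    """One component's assembled momentum system.

    ``S`` (CSR, positive diagonal, nonpositive off-diagonals, <= 7 nnz/row)
    and ``f`` act on the stacked vector of *active* faces of that component.
    ``f0`` is the right-hand side without the pressure term (used for the
    pseudo-velocity step); ``d_coef`` is the SIMPLER correction coefficient
    ``A_face / a_P`` per active face.
    """

    component: str
    S: sp.csr_matrix
    f: np.ndarray
    f0: np.ndarray
    d_coef: np.ndarray


# ---------------------------------------------------------------------------
# Boundary conditions and active unknown sets
# ---------------------------------------------------------------------------

_WALL_BC_KINDS = ("noslip", "slip")


@dataclasses.dataclass
class BoundaryConditions:
    """Fixed face values plus domain-boundary wall treatment.

    ``fixed`` holds one full face-grid array per component; its values are
    used wherever a face is not an unknown (walls, inlet/outlet planes).
    ``domain_walls`` maps boundary names (``"x-","x+","y-","y+","z-","z+"``)
    to either ``"noslip"`` (default), ``"slip"``, or a 3-tuple tangential
    wall velocity (m/s) for a moving wall such as a driven lid.
    """

    fixed: tuple[np.ndarray, np.ndarray, np.ndarray]
    domain_walls: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def zeros(cls, grid: GridSpec) -> "BoundaryConditions":
        return cls(tuple(np.zeros(grid.face_shape(ax)) for ax in range(3)))

    def wall_spec(self, name: str):
        return self.domain_walls.get(name, "noslip")

    def check(self, grid: GridSpec, mask: LumenMask) -> None:
        for ax in range(3):
            if self.fixed[ax].shape != grid.face_shape(ax):
                raise ValueError("boundary profile shape mismatch")
            if not np.isfinite(self.fixed[ax]).all():
                raise ValueError("boundary profile contains non-finite values")
        for name, spec in self.domain_walls.items():
            if name not in ("x-", "x+", "y-", "y+", "z-", "z+"):
                raise ValueError(f"unknown domain boundary {name!r}")
            if isinstance(spec, str) and spec not in _WALL_BC_KINDS:
                raise ValueError(f"unknown wall kind {spec!r}")

    def enforce_global_balance(self, grid: GridSpec, mask: LumenMask) -> float:
        """Rescale outlet w so total outflux equals total influx.

        Dirichlet velocities on every open boundary overdetermine global mass
        balance; measured (noisy) profiles never balance exactly, which would
        make the pressure problem incompatible.  Returns the scale applied.
        """
        u, v, w = self.fixed
        inlet_cells = mask.inlet
        outlet_cells = mask.outlet
        if not inlet_cells.any() or not outlet_cells.any():
            return 1.0
        area = grid.dx * grid.dy
        fl = mask.fluid
        # the FLUID region's Dirichlet boundary: INLET->FLUID faces at k=1
        # and FLUID->OUTLET faces at k=nz-1 (wall-adjacent faces carry 0)
        in_sel = inlet_cells[:, :, 0] & fl[:, :, 1]
        out_sel = fl[:, :, -2] & outlet_cells[:, :, -1]
        influx = float(w[:, :, 1][in_sel].sum()) * area
        outflux = float(w[:, :, -2][out_sel].sum()) * area
        if outflux == 0.0:
            raise ValueError("outlet profile carries zero flux; cannot balance")
        scale = influx / outflux
        sel = outlet_cells[:, :, -1]
        w[:, :, -1][sel] *= scale
        w[:, :, -2][out_sel] *= scale
        return scale


@dataclasses.dataclass
class ActiveSets:
    """Precomputed unknown-face bookkeeping shared by all solver stages."""

    grid: GridSpec
    mask: LumenMask
    active: tuple[np.ndarray, np.ndarray, np.ndarray]  # bool, face grids
    index: tuple[np.ndarray, np.ndarray, np.ndarray]   # int, -1 where fixed
    n_unknowns: tuple[int, int, int]
    fluid_index: np.ndarray  # int, cell grid, -1 outside FLUID
    n_fluid: int

    @classmethod
    def build(cls, grid: GridSpec, mask: LumenMask) -> "ActiveSets":
        mask.validate(grid)
        fl = mask.fluid
        active, index, counts = [], [], []
        for ax in range(3):
            a = np.zeros(grid.face_shape(ax), dtype=bool)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            inner = [slice(None)] * 3
            inner[ax] = slice(1, -1)
            both_fluid = fl[tuple(sl_lo)] & fl[tuple(sl_hi)]
            a[tuple(inner)] = both_fluid
            idx_flat = np.full(a.size, -1, dtype=np.int64)
            flat_active = a.reshape(-1, order="F")
            idx_flat[flat_active] = np.arange(flat_active.sum())
            idx = idx_flat.reshape(a.shape, order="F")
            active.append(a)
            index.append(idx)
            counts.append(int(flat_active.sum()))
        fidx_flat = np.full(grid.n_cells, -1, dtype=np.int64)
        flf = fl.reshape(-1, order="F")
        fidx_flat[flf] = np.arange(flf.sum())
        fluid_index = fidx_flat.reshape(grid.shape, order="F")
        return cls(grid, mask, tuple(active), tuple(index),
                   tuple(counts), fluid_index, int(flf.sum()))

    def gather(self, ax: int, full: np.ndarray) -> np.ndarray:
        """Active-face values of a full face-grid array, stacked order."""
        return full.reshape(-1, order="F")[self.active[ax].reshape(-1, order="F")]

    def scatter(self, ax: int, vec: np.ndarray, full: np.ndarray) -> None:
        """Write a stacked unknown vector back into the full face array."""
        flat = full.reshape(-1, order="F")
        flat[self.active[ax].reshape(-1, order="F")] = vec
        full[...] = flat.reshape(full.shape, order="F")


def bc_from_profiles(components, grid: GridSpec, mask: LumenMask,
                     sets: ActiveSets) -> BoundaryConditions:
    """Boundary conditions from cell-centered velocity volumes.

    Interpolates the three components onto the staggered faces, keeps the
    values on the fixed (non-unknown) faces — this is how measured PC-MRI
    velocities at the boundary z-planes become inlet/outlet Dirichlet data —
    and re-imposes no-slip zeros on every face touching a WALL cell.
    """
    from .grid import centers_to_stagger

    stag = centers_to_stagger(*components, grid)
    bc = BoundaryConditions.zeros(grid)
    wall = mask.wall
    for ax in range(3):
        fixed = ~sets.active[ax]
        bc.fixed[ax][fixed] = stag.component(ax)[fixed]
        adj = np.zeros(grid.face_shape(ax), dtype=bool)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        adj[tuple(sl_lo)] |= wall
        adj[tuple(sl_hi)] |= wall
        bc.fixed[ax][adj] = 0.0
    return bc


def apply_fixed(state: StaggeredVelocityField, bc: BoundaryConditions,
                sets: ActiveSets) -> None:
    """Impose the fixed (non-unknown) face values on a state in place."""
    for ax in range(3):
        comp = state.component(ax)
        fixed = ~sets.active[ax]
        comp[fixed] = bc.fixed[ax][fixed]


# ---------------------------------------------------------------------------
# Momentum assembly (power-law scheme)
# ---------------------------------------------------------------------------

def _power_law(D: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Patankar power-law diffusion weight D * max(0, (1 - 0.1|P|)^5)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(D > 0, np.abs(F) / np.where(D > 0, D, 1.0), np.inf)
    w = np.maximum(0.0, (1.0 - 0.1 * P)) ** 5
    return np.where(D > 0, D * np.where(np.isfinite(P), w, 0.0), 0.0)


_COMP_NAMES = ("u", "v", "w")
_BOUNDARY_NAMES = {(0, -1): "x-", (0, +1): "x+",
                   (1, -1): "y-", (1, +1): "y+",
                   (2, -1): "z-", (2, +1): "z+"}


def assemble_momentum(
    component: int | str,
    state: StaggeredVelocityField,
    pressure: np.ndarray,
    props: FluidProperties,
    grid: GridSpec,
    mask: LumenMask,
    cfg: SolverConfig,
    sets: ActiveSets,
    bc: BoundaryConditions,
    state_old: StaggeredVelocityField | None = None,
) -> MomentumSystem:
    """Assemble one component's sparse momentum system over active faces.

    ``state`` supplies the advecting field of the previous iteration (its
    fixed faces must already carry the boundary values); ``state_old`` the
    previous pseudo-time level for the transient term (defaults to
    ``state``).  Under-relaxation is folded into the diagonal and RHS.
    """
    if isinstance(component, str):
        d = _COMP_NAMES.index(component)
    else:
        d = int(component)
    if state_old is None:
        state_old = state
    state.check(grid)
    for ax in range(3):
        if not np.isfinite(state.component(ax)).all():
            raise ValueError("NaN/Inf in advecting state")

    h = grid.spacing
    rho, mu = props.rho, props.mu
    dV = grid.cell_volume
    act = sets.active[d]
    idx = sets.index[d]
    n = sets.n_unknowns[d]
    U = state.component(d)
    fshape = U.shape

    # face areas: A[d] normal to d, transverse areas for the other axes
    area = [h[1] * h[2], h[0] * h[2], h[0] * h[1]]

    ga = np.nonzero(act)
    gi = np.stack(ga, axis=1)  # (n, 3) face indices, but order of nonzero is C
    # reorder rows to stacked (Fortran) order
    order = np.argsort(idx[ga])
    gi = gi[order]
    rows = np.arange(n)

    aP = np.full(n, rho * dV / cfg.dt)
    b0 = rho * dV / cfg.dt * state_old.component(d)[tuple(gi.T)]
    coo_r, coo_c, coo_v = [], [], []

    P_cell = gi.copy()
    P_cell[:, d] -= 1  # cell on the minus side
    E_cell = gi  # cell on the plus side

    for t in range(3):
        A_t = area[t]
        if t == d:
            D = mu * A_t / h[t]
            # convective fluxes through CV boundaries at cell centers
            vals = U
            up = gi.copy(); up[:, d] += 1
            dn = gi.copy(); dn[:, d] -= 1
            F_plus = rho * A_t * 0.5 * (vals[tuple(gi.T)] + vals[tuple(up.T)])
            F_minus = rho * A_t * 0.5 * (vals[tuple(dn.T)] + vals[tuple(gi.T)])
            for sgn, nb, F in ((+1, up, F_plus), (-1, dn, F_minus)):
                a = _power_law(np.full(n, D), F) + np.maximum(-sgn * F, 0.0)
                nb_idx = idx[tuple(nb.T)]
                live = nb_idx >= 0
                coo_r.append(rows[live])
                coo_c.append(nb_idx[live])
                coo_v.append(-a[live])
                fx = ~live
                b0[fx] += a[fx] * U[tuple(nb[fx].T)]
                aP += a
        else:
            D = mu * A_t / h[t]
            V = state.component(t)
            # faces of component t above/below cells P and E
            for sgn in (+1, -1):
                nb = gi.copy(); nb[:, t] += sgn
                inside = (nb[:, t] >= 0) & (nb[:, t] <= fshape[t] - 1)
                # convecting velocity through the CV boundary
                pf = P_cell.copy()
                ef = E_cell.copy()
                if sgn > 0:
                    pf[:, t] += 1
                    ef[:, t] += 1
                # clamp for safe indexing; flux at clamped (domain) rows is 0
                pfc = np.clip(pf, 0, np.array(V.shape) - 1)
                efc = np.clip(ef, 0, np.array(V.shape) - 1)
                F = rho * A_t * 0.5 * (V[tuple(pfc.T)] + V[tuple(efc.T)])
                valid_f = (pf[:, t] >= 0) & (pf[:, t] <= V.shape[t] - 1)
                F = np.where(valid_f, F, 0.0)

                a = _power_law(np.full(n, D), F) + np.maximum(-sgn * F, 0.0)

                nbc = np.clip(nb, 0, np.array(fshape) - 1)
                nb_idx = np.where(inside, idx[tuple(nbc.T)], -1)

                # classify: wall-interior neighbor faces (both cells WALL)
                pcell_n = P_cell.copy(); pcell_n[:, t] += sgn
                ecell_n = E_cell.copy(); ecell_n[:, t] += sgn
                shp = np.array(grid.shape)
                cin = (
                    (pcell_n[:, t] >= 0) & (pcell_n[:, t] <= shp[t] - 1)
                )
                pcc = np.clip(pcell_n, 0, shp - 1)
                ecc = np.clip(ecell_n, 0, shp - 1)
                lab = mask.labels
                wall_interior = inside & cin & (
                    (lab[tuple(pcc.T)] != FLUID) & (lab[tuple(ecc.T)] != FLUID)
                    & (lab[tuple(pcc.T)] == 0) & (lab[tuple(ecc.T)] == 0)
                )

                live = nb_idx >= 0
                # domain boundary treatment
                dom = ~inside
                bname = _BOUNDARY_NAMES[(t, sgn)]
                spec = bc.wall_spec(bname)

                # matrix entries
                coo_r.append(rows[live])
                coo_c.append(nb_idx[live])
                coo_v.append(-a[live])
                aP += np.where(live, a, 0.0)

                # fixed in-grid neighbors, not wall-interior: fold face value
                fx = inside & ~live & ~wall_interior
                if fx.any():
                    vals_nb = U[tuple(nbc[fx].T)] * 0.0
                    vals_nb = bc.fixed[d][tuple(nbc[fx].T)]
                    b0[fx] += a[fx] * vals_nb
                    aP += np.where(fx, a, 0.0)

                # wall-interior neighbors: no-slip at the half-cell wall plane
                if wall_interior.any():
                    a_g = 2.0 * D  # diffusion only; F across a wall is 0
                    aP += np.where(wall_interior, a_g, 0.0)
                    # tangential wall velocity is zero for interior walls

                # domain boundary: noslip/slip/moving wall at half spacing
                if dom.any():
                    if spec == "slip":
                        pass  # zero flux, zero shear: no contribution
                    else:
                        a_g = 2.0 * D
                        aP += np.where(dom, a_g, 0.0)
                        if not isinstance(spec, str):
                            vwall = float(spec[d])
                            b0 += np.where(dom, a_g * vwall, 0.0)

    # pressure-gradient contribution: A_d * (p_P - p_E)
    pP = pressure[tuple(P_cell.T)]
    pE = pressure[tuple(E_cell.T)]
    grad = area[d] * (pP - pE)

    # under-relaxation: aP/alpha; anchor on the current value of the unknown
    alpha = cfg.relax_u
    aP_rel = aP / alpha
    u_cur = U[tuple(gi.T)]
    b_relax = (aP_rel - aP) * u_cur

    S = sp.coo_matrix(
        (
            np.concatenate([aP_rel] + coo_v),
            (
                np.concatenate([rows] + coo_r),
                np.concatenate([rows] + coo_c),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    S.sum_duplicates()

    f0 = b0 + b_relax
    f = f0 + grad
    d_coef = area[d] / aP_rel
    return MomentumSystem(_COMP_NAMES[d], S, f, f0, d_coef)


# ---------------------------------------------------------------------------
# Linear solvers
# ---------------------------------------------------------------------------

def solve_sparse(S: sp.spmatrix, f: np.ndarray, lin_tol: float = 1e-8,
                 x0: np.ndarray | None = None) -> np.ndarray:
    """Solve ``S x = f`` with BiCGStab (Jacobi preconditioned), warm-started.

    Falls back to a sparse direct factorization if the Krylov iteration
    stagnates; raises :class:`LinearSolveError` if the residual still exceeds
    ``lin_tol`` (relative).
    """
    S = S.tocsr()
    if S.shape[0] != S.shape[1] or S.shape[0] != len(f):
        raise ValueError("dimension mismatch in solve_sparse")
    nf = np.linalg.norm(f)
    if nf == 0.0:
        return np.zeros_like(f)
    diag = S.diagonal()
    if np.any(diag == 0):
        M = None
    else:
        inv = 1.0 / diag
        M = spla.LinearOperator(S.shape, matvec=lambda x: inv * x)
    x, info = spla.bicgstab(S, f, x0=x0, rtol=lin_tol * 0.1, atol=0.0,
                            maxiter=2000, M=M)
    res = np.linalg.norm(S @ x - f) / nf
    if res > lin_tol:
        try:
            x = spla.spsolve(S.tocsc(), f)
        except Exception as exc:  # singular matrix
            raise LinearSolveError(f"linear solve failed: {exc}", res) from exc
        res = np.linalg.norm(S @ x - f) / nf
        if not np.isfinite(res) or res > max(lin_tol, 1e-10):
            raise LinearSolveError(
                f"linear solve residual {res:.3e} exceeds tolerance", res)
    return x


def _pressure_matrix(sets: ActiveSets, d_full: list[np.ndarray]):
    """Assemble the pressure / pressure-correction matrix over FLUID cells.

    Coefficient through each active face is ``d_face * A_face`` (volumetric
    flux response to a unit pressure difference); fixed faces contribute
    nothing (homogeneous Neumann behind Dirichlet velocities).  The first
    FLUID cell is pinned to zero to fix the Neumann nullspace.
    """
    grid = sets.grid
    h = grid.spacing
    area = [h[1] * h[2], h[0] * h[2], h[0] * h[1]]
    nf = sets.n_fluid
    fidx = sets.fluid_index
    fl = sets.mask.fluid
    cells = np.nonzero(fl)
    ci = np.stack(cells, axis=1)
    order = np.argsort(fidx[cells])
    ci = ci[order]
    rows = np.arange(nf)

    aP = np.zeros(nf)
    rr, cc, vv = [], [], []
    for ax in range(3):
        for sgn in (+1, -1):
            face = ci.copy()
            if sgn > 0:
                face[:, ax] += 1
            coef = d_full[ax][tuple(face.T)] * area[ax]
            nb = ci.copy()
            nb[:, ax] += sgn
            shp = np.array(grid.shape)
            inb = (nb[:, ax] >= 0) & (nb[:, ax] <= shp[ax] - 1)
            nbc = np.clip(nb, 0, shp - 1)
            nb_idx = np.where(inb, fidx[tuple(nbc.T)], -1)
            live = (nb_idx >= 0) & (coef > 0)
            rr.append(rows[live])
            cc.append(nb_idx[live])
            vv.append(-coef[live])
            aP += np.where(live, coef, 0.0)
    A = sp.coo_matrix(
        (np.concatenate([aP] + vv),
         (np.concatenate([rows] + rr), np.concatenate([rows] + cc))),
        shape=(nf, nf)).tocsr()
    A.sum_duplicates()
    # pin the first fluid cell: overwrite its row with identity
    A = A.tolil()
    A.rows[0] = [0]
    A.data[0] = [1.0]
    return A.tocsr(), ci


def _mass_imbalance(sets: ActiveSets, vel_full: list[np.ndarray], ci) -> np.ndarray:
    """Net volumetric efflux per FLUID cell (m^3/s), stacked order."""
    grid = sets.grid
    h = grid.spacing
    area = [h[1] * h[2], h[0] * h[2], h[0] * h[1]]
    out = np.zeros(len(ci))
    for ax in range(3):
        hi = ci.copy(); hi[:, ax] += 1
        out += area[ax] * (vel_full[ax][tuple(hi.T)] - vel_full[ax][tuple(ci.T)])
    return out


def solve_pressure(rhs: np.ndarray, lu, pin_value: float = 0.0) -> np.ndarray:
    """Solve the assembled pressure system (factorized) for one RHS.

    The pinned cell's RHS entry is replaced by ``pin_value``.
    """
    b = rhs.copy()
    b[0] = pin_value
    return lu.solve(b)


def poisson_pressure_system(grid: GridSpec, mask: LumenMask, coef: float = 1.0):
    """Uniform-coefficient pressure Poisson system (for verification).

    Builds the same masked Neumann/pinned operator with a constant face
    coefficient ``coef`` on every FLUID–FLUID face, so that for an all-FLUID
    box it discretizes ``coef * laplace(p)`` (times cell volume).  Returns
    ``(A, cells)`` with cells in stacked order.
    """
    sets = ActiveSets.build(grid, mask)
    d_full = []
    h = grid.spacing
    for ax in range(3):
        d = np.zeros(grid.face_shape(ax))
        d[sets.active[ax]] = coef / h[ax]
        d_full.append(d)
    return _pressure_matrix(sets, d_full)


# ---------------------------------------------------------------------------
# SIMPLER iteration and pseudo-transient outer loop
# ---------------------------------------------------------------------------

def _full_with(sets: ActiveSets, ax: int, vec: np.ndarray,
               template: np.ndarray) -> np.ndarray:
    out = template.copy()
    sets.scatter(ax, vec, out)
    return out


def simpler_iteration(
    state: StaggeredVelocityField,
    pressure: np.ndarray,
    props: FluidProperties,
    grid: GridSpec,
    mask: LumenMask,
    cfg: SolverConfig,
    sets: ActiveSets,
    bc: BoundaryConditions,
    state_old: StaggeredVelocityField | None = None,
    reg=None,
):
    """One full SIMPLER pass; returns ``(state, pressure, residual)``.

    ``residual`` is the max-norm divergence (1/s) of the starred field over
    FLUID cells, i.e. the mass imbalance before the velocity correction.
    When ``reg`` (a prepared assimilation problem, see
    :func:`flowfuse.regularization.prepare_assimilation`) is given, the
    momentum solves for components with positive weight become regularized
    least-squares solves.
    """
    from .regularization import regularized_solve  # local import, no cycle

    systems = []
    for ax in range(3):
        if sets.n_unknowns[ax] == 0:
            systems.append(None)
            continue
        systems.append(assemble_momentum(
            ax, state, pressure, props, grid, mask, cfg, sets, bc,
            state_old=state_old))

    # step 1: pseudo-velocities  u_hat = (b0 - S_off x) / diag
    hat_full = []
    for ax in range(3):
        comp = state.component(ax)
        if systems[ax] is None:
            hat_full.append(comp.copy())
            continue
        sysm = systems[ax]
        x = sets.gather(ax, comp)
        diag = sysm.S.diagonal()
        hat = x - (sysm.S @ x - sysm.f0) / diag
        hat_full.append(_full_with(sets, ax, hat, comp))

    # pressure matrix shared by steps 2 and 4
    d_full = []
    for ax in range(3):
        d = np.zeros(grid.face_shape(ax))
        if systems[ax] is not None:
            sets.scatter(ax, systems[ax].d_coef, d)
        d_full.append(d)
    A_p, ci = _pressure_matrix(sets, d_full)
    lu = spla.splu(A_p.tocsc())

    # step 2: pressure equation from pseudo-velocity imbalance
    b_hat = -_mass_imbalance(sets, hat_full, ci)
    p_vec = solve_pressure(b_hat, lu)
    p_new = np.zeros(grid.shape)
    p_new[tuple(ci.T)] = p_vec
    if cfg.relax_p < 1.0:
        p_new = pressure + cfg.relax_p * (p_new - pressure)
        p_new[mask.fluid] -= p_new[tuple(ci[0])]  # keep pin at 0

    # step 3: momentum solves with the new pressure -> starred velocities
    star_full = []
    star = StaggeredVelocityField(*[state.component(ax).copy() for ax in range(3)])
    for ax in range(3):
        if systems[ax] is None:
            star_full.append(star.component(ax))
            continue
        sysm = systems[ax]
        # rebuild pressure term with updated pressure
        gi = np.stack(np.nonzero(sets.active[ax]), axis=1)
        order = np.argsort(sets.index[ax][sets.active[ax]])
        gi = gi[order]
        Pc = gi.copy(); Pc[:, ax] -= 1
        h = grid.spacing
        area = [h[1] * h[2], h[0] * h[2], h[0] * h[1]]
        grad = area[ax] * (p_new[tuple(Pc.T)] - p_new[tuple(gi.T)])
        fvec = sysm.f0 + grad
        x0 = sets.gather(ax, state.component(ax))
        lam = 0.0 if reg is None else reg.lam[ax]
        if reg is not None and lam > 0:
            x = regularized_solve(
                dataclasses.replace(sysm, f=fvec), reg.G[ax], lam,
                reg.m[ax], cfg.lin_tol, x0)
        else:
            x = solve_sparse(sysm.S, fvec, cfg.lin_tol, x0)
        sets.scatter(ax, x, star.component(ax))
        star_full.append(star.component(ax))

    # inner residual: mass imbalance of the starred field
    b_star = -_mass_imbalance(sets, star_full, ci)
    dV = grid.cell_volume
    residual = float(np.max(np.abs(b_star)) / dV) if len(b_star) else 0.0

    # step 4: pressure-correction equation
    pc_vec = solve_pressure(b_star, lu)
    pc = np.zeros(grid.shape)
    pc[tuple(ci.T)] = pc_vec

    # step 5: velocity correction on active faces
    for ax in range(3):
        if systems[ax] is None:
            continue
        gi = np.stack(np.nonzero(sets.active[ax]), axis=1)
        order = np.argsort(sets.index[ax][sets.active[ax]])
        gi = gi[order]
        Pc = gi.copy(); Pc[:, ax] -= 1
        corr = systems[ax].d_coef * (pc[tuple(Pc.T)] - pc[tuple(gi.T)])
        x = sets.gather(ax, star.component(ax)) + corr
        sets.scatter(ax, x, star.component(ax))

    return star, p_new, residual


@dataclasses.dataclass
class SolverResult:
    """Converged (or capped) solver output with iteration accounting."""

    state: StaggeredVelocityField
    pressure: np.ndarray
    outer_steps: int
    inner_iterations: list[int]
    residual_history: list[float]   # final inner continuity residual per step
    rate_history: list[float]       # ||dv||_rms / dt per outer step
    converged: bool

    @property
    def total_inner(self) -> int:
        return int(sum(self.inner_iterations))


def _plug_initial(grid: GridSpec, mask: LumenMask, bc: BoundaryConditions,
                  sets: ActiveSets) -> StaggeredVelocityField:
    """Plug profile matching the inlet flux, as the initial velocity guess."""
    state = StaggeredVelocityField.zeros(grid)
    inlet = mask.inlet[:, :, 0]
    if inlet.any():
        w_in = bc.fixed[2][:, :, 0]
        mean_w = float(w_in[inlet].mean())
    else:
        mean_w = 0.0
    state.w[sets.active[2]] = mean_w
    apply_fixed(state, bc, sets)
    return state


def run_steady_state(
    props: FluidProperties,
    grid: GridSpec,
    mask: LumenMask,
    cfg: SolverConfig,
    bc: BoundaryConditions,
    initial: StaggeredVelocityField | str = "plug",
    reg=None,
    balance_flux: bool = True,
    callback=None,
) -> SolverResult:
    """March SIMPLER in pseudo-time to the steady state.

    Each outer step runs inner SIMPLER iterations until the pre-correction
    continuity residual drops below ``cfg.div_tol`` (or ``max_inner`` is
    hit), then advances pseudo-time; the loop stops when the update rate
    ``||v(t+dt) - v(t)||_rms / dt`` falls below ``cfg.eps`` or ``max_outer``
    is reached (in which case the result is flagged not converged).
    """
    sets = ActiveSets.build(grid, mask)
    bc.check(grid, mask)
    if balance_flux:
        bc.enforce_global_balance(grid, mask)

    if isinstance(initial, str):
        if initial == "plug":
            state = _plug_initial(grid, mask, bc, sets)
        elif initial == "zero":
            state = StaggeredVelocityField.zeros(grid)
            apply_fixed(state, bc, sets)
        else:
            raise ValueError(f"unknown initial guess {initial!r}")
    else:
        state = initial.copy()
        apply_fixed(state, bc, sets)

    pressure = np.zeros(grid.shape)
    inner_counts: list[int] = []
    res_hist: list[float] = []
    rate_hist: list[float] = []
    n_act = sum(sets.n_unknowns)
    converged = False

    for outer in range(1, cfg.max_outer + 1):
        state_old = state.copy()
        residual = np.inf
        inner = 0
        while inner < cfg.max_inner:
            state, pressure, residual = simpler_iteration(
                state, pressure, props, grid, mask, cfg, sets, bc,
                state_old=state_old, reg=reg)
            inner += 1
            if residual <= cfg.div_tol:
                break
        inner_counts.append(inner)
        res_hist.append(residual)

        diff2 = 0.0
        for ax in range(3):
            d = state.component(ax)[sets.active[ax]] \
                - state_old.component(ax)[sets.active[ax]]
            diff2 += float(d @ d)
        rate = np.sqrt(diff2 / max(n_act, 1)) / cfg.dt
        rate_hist.append(float(rate))
        if callback is not None:
            callback(outer, residual, rate)
        if rate < cfg.eps:
            converged = True
            break

    return SolverResult(state, pressure, len(inner_counts), inner_counts,
                        res_hist, rate_hist, converged)
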