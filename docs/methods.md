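# Methods

## Flow model and discretization

Blood is modeled as an incompressible, isothermal Newtonian fluid with
constant density `rho` and dynamic viscosity `mu`; body forces are
neglected and walls are rigid.  The unknowns are the three velocity
components `u, v, w` and the pressure `p` on a uniform Cartesian grid of
`nx x ny x nz` pressure cells.  Velocities are staggered by half a grid
spacing onto cell faces (MAC arrangement), which couples pressure and
velocity compactly and excludes checkerboard pressure modes.  The linear
stacking convention for all matrices and vectors is x fastest, then y,
then z.

Momentum is discretized with the finite-volume power-law
convection–diffusion scheme.  For each component this yields a sparse
system `S x = f` with at most seven nonzeros per row (hepta-diagonal): the
diagonal carries the sum of the face conductances plus the pseudo-transient
term `rho dV / dt`, off-diagonals are the negated conductances, and `f`
collects the previous-level transient contribution, folded Dirichlet
neighbors, and the pressure-difference term.  The advecting field and the
coefficients lag one iteration (Picard linearization); no inner Newton loop
is used.

### Geometry: masked box with eliminated exterior

The computational domain is a rectangular box carrying a lumen mask with
cell labels WALL / FLUID / INLET / OUTLET (inlet and outlet are one-cell
layers on the two boundary z-planes).  Unknowns are only the faces between
two FLUID cells and the FLUID pressure cells; everything else is eliminated
from the systems rather than solved-and-masked, so the matrix dimension per
component is the number of active faces, not `N = nx ny nz`.  Fixed faces
carry Dirichlet data: zero on wall-adjacent faces (no-slip) and
interpolated measured profiles on the inlet/outlet planes.  Tangential
no-slip at interior wall cells is imposed by a ghost value at the half-cell
wall plane (conductance `2 mu A / h`), a first-order immersed treatment;
domain boundaries accept `noslip`, `slip`, or a prescribed tangential wall
velocity (used for the lid-driven cavity).

The staircase wall of a voxelized circular lumen is the dominant error
source near the wall: on a 16^3-cell cross-section the wall-adjacent cells
of a Poiseuille flow carry up to ~5% of the peak velocity in error while
the diametral profiles through the axis agree with the analytic parabola to
~1.3%.  Validation therefore reports both the diametral-profile error (the
conventional profile-validation cut) and the full-lumen maximum.

### SIMPLER iteration and pseudo-transient continuation

Each pseudo-time step is converged by SIMPLER inner iterations:
pseudo-velocities from the momentum coefficients (no pressure term); a
pressure equation driven by the pseudo-velocity mass imbalance; momentum
solves for starred velocities using that pressure; a pressure-correction
equation from the starred-velocity imbalance; and a velocity correction
that restores discrete continuity exactly (to the accuracy of the direct
pressure factorization, in practice ~1e-12 s^-1).  The reported inner
residual is the max-norm divergence of the starred field, which vanishes as
the nonlinear iteration converges; `div_tol` bounds it.  The pressure and
pressure-correction solves share one sparse LU factorization per inner
iteration; the Neumann nullspace is fixed by pinning the first FLUID cell
to zero.  Momentum systems are solved with BiCGStab (Jacobi-preconditioned,
warm-started from the previous iterate, relative tolerance `lin_tol`,
direct fallback on stagnation).

The outer loop advances pseudo-time `dt` with fixed boundary data and stops
when the update rate `||v(t+dt) - v(t)||_rms / dt` drops below `eps`
(units m/s^2).  The RMS norm over active faces is used so the criterion
does not scale with the grid size.  Caps (`max_outer`, `max_inner`) flag
the result as non-converged rather than silently returning.  Iteration
counts are recorded both as outer pseudo-time steps and as total inner
iterations, since either can be meant by "iterations to convergence" in
comparisons between solver modes.

Choices where standard practice had to fill a gap: under-relaxation of the
momentum equations with `relax_u = 0.7` (folded into the diagonal and RHS,
consistently reused for the pressure-correction coefficients); no pressure
under-relaxation by default (`relax_p = 1`), since SIMPLER obtains the
pressure from its own equation rather than from a correction; initial guess
is a plug profile carrying the inlet mean velocity (a zero start and warm
restarts are also supported).

### Boundary data and global mass balance

All three measured velocity components on the boundary z-planes serve as
inlet and outlet Dirichlet data.  Because Dirichlet velocities on every
open boundary overdetermine global mass conservation — and noisy
measurements never balance exactly — the outlet w-profile is rescaled so
the flux through the FLUID region's Dirichlet boundary (the INLET->FLUID
faces at k=1 and FLUID->OUTLET faces at k=nz-1) balances exactly;
otherwise the incompatibility concentrates at the pinned pressure cell as a
spurious divergence.

## Measurement model and regularization

A 3DFT Cartesian PC-MRI acquisition measures each component blurred by the
point-spread function of its finite k-space coverage, the separable sinc
`psi(x,y,z) = sinc(x/dx_m) sinc(y/dy_m) sinc(z/dz_m)` truncated to
`|x| <= 2 dx_m` etc. (voxel spacings `dx_m, dy_m, dz_m`).  The operator
`Gamma` samples this kernel at CFD-cell offsets per MRI voxel, axis by
axis, as a Kronecker product of 1-D operators.  Rows are normalized to unit
sum so constant fields are preserved — the kernel itself does not integrate
to one on a discrete stencil, and a velocity-to-velocity map must have unit
DC gain; edge rows are renormalized over their truncated support.  When the
grids coincide the identity can be requested explicitly (the high-resolution
same-grid configuration).  Rows for unmeasured voxels are simply omitted
(`M < N`), which is also how partial-coverage protocols are expressed.

Momentum unknowns are staggered face values while measurements are
cell-centered, so the penalty actually applied is
`||Gamma A x - m~||^2` with `A` the face-to-center averaging map and `m~`
the measurement minus the (fixed) boundary-face contribution.  This
composition preserves the closed form of the regularized solution with
`Gamma <- Gamma A` and is the minimal consistent reading of a penalty that
compares solver velocities with voxel values.

The minimizer of `1/2||Sx - f||^2 + lambda/2||Gx - m||^2` is computed
iteratively on the stacked least-squares form `[S; sqrt(lambda) G] x ~
[f; sqrt(lambda) m]` with LSMR (warm-started; the normal matrix is never
formed).  The optimality gradient `S'(Sx-f) + lambda G'(Gx-m)` is checked
after the solve and the iteration restarts at tighter tolerance until it
falls below `1e-6 ||S'f||`; `lambda = 0` short-circuits to the plain
Krylov momentum solve, so the assimilating solver with all weights zero is
bitwise the pure-CFD pathway.

`lambda` values are dimensional in the sense that they weigh `||Gx - m||^2`
(velocity units) against `||Sx - f||^2` (whose scale is set by the momentum
coefficients, dominated by `rho dV / dt`).  The working values — 1 for the
mode comparisons, 5e-9…5e-6 for the denoising study — therefore assume the
reference discretization (0.5 x 0.5 x 1.0 mm voxels, `dt` = 0.1 ms,
`rho` = 1100 kg/m^3), which the corresponding experiment profiles keep.

## Synthetic data

The generator emulates the measurement chain: analytic staggered truth
field -> face-to-center averaging -> truncated-sinc blur and resampling (on
the same grid this degenerates to the identity) -> per-component i.i.d.
zero-mean Gaussian noise (sigma default 8 cm/s, per-component substreams
spawned from one seed) -> optional single-period VENC wrapping -> optional
linear offset `a x + b y + c z + d` per component.  Convolution uses
zero-filled exterior values, consistent with velocities vanishing outside
the body.  It does not emulate k-space raw data, coil sensitivities,
magnitude-dependent noise, eddy-current physics beyond the linear term, or
time-resolved acquisitions — so passing tests validate the solver and the
linear signal model, not robustness to those effects in vivo.

Phantom geometries are a voxelized circular pipe and a planar Y
bifurcation (parent radius 2.2 mm splitting into two 1.4 mm branches,
carotid-like scale), with parabolic inlet profiles
`w = w_max (1 - (r/R)^q)`, `q = 2`.  Peak velocities default to 0.4 m/s
(systolic carotid scale; Reynolds number a few hundred).  For the denoising
study the truth profile uses `q = 4`: a blunted, plug-like profile of the
kind shear-thinning blood develops, which a constant-viscosity solver
cannot reproduce exactly.  This deliberately injects model mismatch between
the truth and the Newtonian solver — the regime the combined method
addresses — so the lambda sweep exhibits the real trade-off: small lambda
approaches pure CFD (model error), large lambda approaches the noisy
measurement (noise error), and an interior lambda is optimal.  Measured
sweep on the default phantom (sigma = 8 cm/s, seed 5): noisy input 5.9 dB,
lambda 0 -> 15.3, 5e-9 -> 15.7, 5e-8 -> 17.3, 5e-7 -> 14.5, 5e-6 ->
10.2 dB against the clean truth.

Static-tissue masks for offset removal default to all non-lumen voxels — a
synthetic stand-in for manually outlined stationary-tissue regions.

## Metrics

SER is computed over the lumen (FLUID cells) by default; summing over the
whole rectangular box would bias the ratio with zero-padding (both options
exist).  Identical fields yield an explicit `+inf` sentinel, serialized as
the string `"inf"`.  Component energy ratios (e.g. the w/u energy gap that
explains why SER_w exceeds SER_u at equal noise) and divergence statistics
(max and RMS over a mask) round out the comparisons.

## Problem sizes and defaults

Desk-scale geometries are used throughout — pipe 16x16x48 (validation) and
10x10x24 (denoising, ~700 lumen voxels), bifurcation 16x16x32, cavity 33^2
and 65^2 — with the pseudo-time step per experiment: 2 ms for the pipe
validation, 1 ms for the mode comparison (lambda = 1 dominates the data
term for any reasonable `dt`), and the reference 0.1 ms for the denoising
study, where the lambda grid is calibrated against the momentum-coefficient
scale.  Steady-state tolerances `eps` are 2e-2…2e-4 m/s^2 depending on the
velocity scale of the experiment.

## Known limitations

Single steady state per run (one cardiac phase); rigid walls; constant
viscosity; uniform grids only (no local refinement, so wall-shear-stress
estimation is out of scope); first-order accuracy at staircase walls;
single-wrap aliasing model; lambda chosen manually (no L-curve/GCV).  The
architecture runs one phase at a time and can be invoked per phase for
time-resolved data, but it performs no temporal coupling.
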