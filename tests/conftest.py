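import numpy as np
import pytest

from flowfuse import (
    ActiveSets,
    BoundaryConditions,
    FluidProperties,
    PhantomSpec,
    SolverConfig,
    build_grid,
    generate_poiseuille,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """5x5x5 unit-spacing grid (mm-scale), all cells fluid-capable."""
    return build_grid((5, 5, 5), (1e-3, 1e-3, 1e-3))


@pytest.fixture
def pipe_setup():
    """Small Poiseuille pipe: grid, spec, mask, analytic truth field."""
    grid = build_grid((10, 10, 20), (0.5e-3, 0.5e-3, 1.0e-3))
    spec = PhantomSpec(kind="pipe", radius=2.0e-3, peak_velocity=0.3)
    mask, truth = generate_poiseuille(spec, grid)
    return grid, spec, mask, truth


@pytest.fixture
def blood():
    return FluidProperties(rho=1060.0, mu=0.0032)


def make_truth_bc(grid, mask, truth):
    """Dirichlet boundary profiles taken from an analytic truth field."""
    sets = ActiveSets.build(grid, mask)
    bc = BoundaryConditions.zeros(grid)
    for ax in range(3):
        fixed = ~sets.active[ax]
        bc.fixed[ax][fixed] = truth.component(ax)[fixed]
    return sets, bc


@pytest.fixture
def quick_cfg():
    return SolverConfig(dt=2e-3, eps=5e-2, div_tol=1.0, max_outer=500,
                        max_inner=6, lin_tol=1e-8)
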