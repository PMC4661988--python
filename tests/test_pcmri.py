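import numpy as np
import pytest

from flowfuse import (
    NoiseModel,
    PhantomSpec,
    build_grid,
    generate_bifurcation,
    generate_poiseuille,
    remove_linear_offset,
    simulate_pcmri,
    stagger_to_centers,
    unwrap_velocity,
    wrap_velocity,
)
from flowfuse.pcmri import lumen_connected_components


class TestPoiseuillePhantom:
    def test_centerline_carries_peak_velocity(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        # the pipe axis passes between cell centers; the maximum face value
        # approaches w_max to within the face-offset sampling error
        r_min = np.hypot(grid.dx / 2, grid.dy / 2)
        w_at_rmin = spec.peak_velocity * (1 - (r_min / spec.radius) ** 2)
        assert truth.w.max() == pytest.approx(w_at_rmin, rel=1e-12)

    def test_velocity_zero_outside_radius(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        from flowfuse.grid import face_centers
        xf, yf, _ = face_centers(grid, 2)
        cx = grid.origin[0] + 0.5 * (grid.nx - 1) * grid.dx
        cy = grid.origin[1] + 0.5 * (grid.ny - 1) * grid.dy
        outside = np.hypot(xf - cx, yf - cy) >= spec.radius
        assert np.all(truth.w[outside] == 0.0)

    def test_mean_velocity_is_half_peak(self, pipe_setup):
        # analytic: <w> over the disc of a parabolic profile = w_max / 2;
        # voxelization error shrinks with resolution, allow a few percent
        grid, spec, mask, truth = pipe_setup
        wc = stagger_to_centers(truth, grid)[2]
        lumen_mid = mask.fluid[:, :, grid.nz // 2]
        mean = wc[:, :, grid.nz // 2][lumen_mid].mean()
        assert mean == pytest.approx(spec.peak_velocity / 2, rel=0.08)

    def test_oversized_pipe_rejected(self):
        grid = build_grid((8, 8, 16), (0.5e-3,) * 3)
        spec = PhantomSpec(kind="pipe", radius=5e-3)
        with pytest.raises(ValueError):
            generate_poiseuille(spec, grid)

    def test_blunted_profile_flatter_than_parabola(self):
        grid = build_grid((12, 12, 16), (0.5e-3, 0.5e-3, 1.0e-3))
        p2 = PhantomSpec(kind="pipe", radius=2.5e-3, profile_exponent=2.0)
        p6 = PhantomSpec(kind="pipe", radius=2.5e-3, profile_exponent=6.0)
        _, t2 = generate_poiseuille(p2, grid)
        _, t6 = generate_poiseuille(p6, grid)
        # the blunted profile is flatter: at least as fast near the axis
        # and with a higher lumen mean
        assert t6.w.max() >= t2.w.max()
        assert t6.w.sum() > 1.2 * t2.w.sum()


class TestBifurcationPhantom:
    @pytest.fixture
    def bif(self):
        grid = build_grid((16, 16, 32), (0.5e-3, 0.5e-3, 1.0e-3))
        spec = PhantomSpec(kind="bifurcation", radius=2.2e-3,
                           branch_radius=1.4e-3, branch_span=4.2e-3,
                           split_fraction=0.4, peak_velocity=0.4)
        mask, truth = generate_bifurcation(spec, grid)
        return grid, spec, mask, truth

    def test_outlet_plane_has_two_open_branches(self, bif):
        grid, spec, mask, truth = bif
        out = mask.outlet[:, :, -1]
        assert out.sum() > 0
        left = out[: grid.nx // 2].sum()
        right = out[grid.nx // 2:].sum()
        assert left > 0 and right > 0

    def test_single_connected_lumen(self, bif):
        grid, spec, mask, truth = bif
        assert lumen_connected_components(mask) == 1

    def test_inlet_flux_matches_analytic_parabola_flux(self, bif):
        grid, spec, mask, truth = bif
        # analytic: integral of w_max(1 - r^2/R^2) over the disc
        area_flux = spec.peak_velocity * np.pi * spec.radius ** 2 / 2
        got = truth.w[:, :, 0].sum() * grid.dx * grid.dy
        assert got == pytest.approx(area_flux, rel=0.05)

    def test_branches_outside_domain_rejected(self):
        grid = build_grid((10, 10, 20), (0.5e-3, 0.5e-3, 1.0e-3))
        spec = PhantomSpec(kind="bifurcation", radius=2e-3,
                           branch_radius=1.5e-3, branch_span=6e-3)
        with pytest.raises(ValueError):
            generate_bifurcation(spec, grid)


class TestSimulatePCMRI:
    def test_degenerate_pipeline_returns_centered_truth(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        meas = simulate_pcmri(truth, grid, noise=NoiseModel(sigma=0.0))
        uc, vc, wc = stagger_to_centers(truth, grid)
        assert np.array_equal(meas.w, wc)
        assert np.array_equal(meas.u, uc)

    def test_noise_standard_deviation_matches_request(self):
        # uniform-velocity volume, sigma = 8 cm/s: the sample sd over many
        # voxels must come out within 10%
        grid = build_grid((12, 12, 12), (1e-3,) * 3)
        from flowfuse import StaggeredVelocityField
        truth = StaggeredVelocityField.zeros(grid)
        truth.w[...] = 0.2
        meas = simulate_pcmri(truth, grid,
                              noise=NoiseModel(sigma=0.08, seed=3, venc=5.0))
        resid = meas.w - 0.2
        assert resid.size >= 1000
        assert np.std(resid) == pytest.approx(0.08, rel=0.10)
        assert np.mean(resid) == pytest.approx(0.0, abs=3 * 0.08 / np.sqrt(resid.size))

    def test_seeded_reproducibility(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        nm = NoiseModel(sigma=0.05, seed=77)
        m1 = simulate_pcmri(truth, grid, noise=nm)
        m2 = simulate_pcmri(truth, grid, noise=nm)
        for a, b in zip(m1.components(), m2.components()):
            assert np.array_equal(a, b)

    def test_components_receive_independent_noise(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        meas = simulate_pcmri(truth, grid, noise=NoiseModel(sigma=0.05, seed=1))
        uc, vc, wc = stagger_to_centers(truth, grid)
        nu, nv = meas.u - uc, meas.v - vc
        corr = np.corrcoef(nu.ravel(), nv.ravel())[0, 1]
        assert abs(corr) < 0.1

    def test_wrap_maps_beyond_venc_values(self):
        venc = 0.5
        assert wrap_velocity(np.array([1.2 * venc]), venc)[0] == \
            pytest.approx(-0.8 * venc)
        assert wrap_velocity(np.array([0.3]), venc)[0] == pytest.approx(0.3)

    def test_wrapping_applied_when_enabled(self):
        grid = build_grid((6, 6, 6), (1e-3,) * 3)
        from flowfuse import StaggeredVelocityField
        truth = StaggeredVelocityField.zeros(grid)
        truth.w[...] = 0.6  # 1.2 * VENC
        nm = NoiseModel(sigma=0.0, venc=0.5, wrap=True)
        meas = simulate_pcmri(truth, grid, noise=nm)
        assert np.allclose(meas.w, -0.4)

    def test_linear_offset_applied(self):
        grid = build_grid((6, 6, 6), (1e-3,) * 3)
        from flowfuse import StaggeredVelocityField
        truth = StaggeredVelocityField.zeros(grid)
        nm = NoiseModel(sigma=0.0, venc=1.0,
                        offset={"u": (0.0, 0.0, 0.0, 0.02)})
        meas = simulate_pcmri(truth, grid, noise=nm)
        assert np.allclose(meas.u, 0.02)
        assert np.allclose(meas.v, 0.0)


class TestUnwrap:
    def test_flagged_wrapped_voxel_restored(self):
        grid = build_grid((4, 4, 4), (1e-3,) * 3)
        from flowfuse import MRIMeasurement
        w = np.full(grid.shape, -0.4)
        meas = MRIMeasurement(np.zeros(grid.shape), np.zeros(grid.shape),
                              w, grid, venc=0.5)
        flag = np.zeros(grid.shape, dtype=bool)
        flag[1, 2, 3] = True
        fixed = unwrap_velocity(meas, flag, components=("w",))
        assert fixed.w[1, 2, 3] == pytest.approx(0.6)  # -0.8*V -> +1.2*V
        assert fixed.w[0, 0, 0] == pytest.approx(-0.4)

    def test_empty_flag_set_is_identity(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        meas = simulate_pcmri(truth, grid, noise=NoiseModel(sigma=0.02, seed=9))
        out = unwrap_velocity(meas, np.zeros(grid.shape, dtype=bool))
        for a, b in zip(out.components(), meas.components()):
            assert np.array_equal(a, b)

    def test_wrap_flag_unwrap_round_trip(self):
        # composition oracle: for |v| < 3*VENC a single wrap is inverted
        # exactly by adding back one period with the matching sign
        venc = 0.5
        grid = build_grid((5, 5, 5), (1e-3,) * 3)
        rng = np.random.default_rng(4)
        from flowfuse import MRIMeasurement
        vtrue = rng.uniform(-1.45, 1.45, size=grid.shape)
        wrapped = wrap_velocity(vtrue, venc)
        meas = MRIMeasurement(wrapped.copy(), np.zeros(grid.shape),
                              np.zeros(grid.shape), grid, venc=venc)
        up = vtrue >= venc
        down = vtrue < -venc
        out = unwrap_velocity(meas, up, components=("u",), direction=+1)
        out = unwrap_velocity(out, down, components=("u",), direction=-1)
        assert np.allclose(out.u, vtrue, atol=1e-12)

    def test_out_of_range_index_rejected(self, pipe_setup):
        grid, spec, mask, truth = pipe_setup
        meas = simulate_pcmri(truth, grid)
        with pytest.raises(ValueError):
            unwrap_velocity(meas, np.array([[99, 0, 0]]))


class TestRemoveLinearOffset:
    def _measurement(self, grid, offset=None, sigma=0.0, seed=0):
        from flowfuse import StaggeredVelocityField
        truth = StaggeredVelocityField.zeros(grid)
        nm = NoiseModel(sigma=sigma, seed=seed, venc=1.0, offset=offset)
        meas = simulate_pcmri(truth, grid, noise=nm)
        meas.static_mask = np.ones(grid.shape, dtype=bool)
        return meas

    def test_zero_offset_input_unchanged(self):
        grid = build_grid((6, 6, 6), (1e-3,) * 3)
        meas = self._measurement(grid)
        out, coeffs = remove_linear_offset(meas)
        assert np.allclose(out.u, 0.0, atol=1e-15)
        assert np.allclose(coeffs["u"], 0.0, atol=1e-12)

    def test_planted_plane_recovered_exactly(self):
        # least-squares oracle: noiseless planted plane must be recovered
        # to round-off
        grid = build_grid((8, 8, 8), (1e-3,) * 3)
        planted = (0.01, -0.02, 0.0, 0.005)
        meas = self._measurement(grid, offset={"u": planted})
        out, coeffs = remove_linear_offset(meas)
        assert np.allclose(coeffs["u"], planted, atol=1e-10)
        assert np.allclose(out.u, 0.0, atol=1e-10)
        assert abs(np.mean(out.u[meas.static_mask])) < 1e-12

    def test_intercept_recovery_within_standard_error(self):
        grid = build_grid((10, 10, 10), (1e-3,) * 3)
        sigma = 0.05
        meas = self._measurement(grid, offset={"u": (0.0, 0.0, 0.0, 0.03)},
                                 sigma=sigma, seed=21)
        _, coeffs = remove_linear_offset(meas)
        n = meas.static_mask.sum()
        assert abs(coeffs["u"][3] - 0.03) < 3 * sigma / np.sqrt(n) * 4

    def test_degenerate_static_region_rejected(self):
        grid = build_grid((6, 6, 6), (1e-3,) * 3)
        meas = self._measurement(grid)
        flat = np.zeros(grid.shape, dtype=bool)
        flat[:, :, 2] = True  # coplanar: z column degenerate
        with pytest.raises(ValueError):
            remove_linear_offset(meas, static_mask=flat)

    def test_too_few_voxels_rejected(self):
        grid = build_grid((6, 6, 6), (1e-3,) * 3)
        meas = self._measurement(grid)
        tiny = np.zeros(grid.shape, dtype=bool)
        tiny[0, 0, 0] = True
        with pytest.raises(ValueError):
            remove_linear_offset(meas, static_mask=tiny)
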