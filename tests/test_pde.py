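"""Forward-model tests: gradient, binding profile, PDE solver, equilibria,
alternation chain and gap measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hurpgap as hg
from hurpgap.exceptions import (ConvergenceError, InvalidParameterError,
                                UndefinedGapError)
from hurpgap.pde import build_operator


class TestRanGradient:
    def test_unity_at_origin_and_exponential_decay(self):
        assert hg.ran_gradient(0.0, 2.0) == 1.0
        assert np.isclose(hg.ran_gradient(2.0, 2.0), np.exp(-1.0))

    @given(x=st.floats(0.01, 50), s=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_semigroup_property(self, x, s):
        # exp(-2x/s) = exp(-x/s)^2
        assert np.isclose(hg.ran_gradient(2 * x, s),
                          hg.ran_gradient(x, s) ** 2, rtol=1e-10)

    def test_invalid_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.ran_gradient(1.0, 0.0)


class TestBindingProfile:
    @pytest.mark.parametrize("x, lam, r, l, expected", [
        (0.0, 1.0, 4.0, 1.0, 0.25),   # lam/r at the kinetochore
        (1.0, 1.0, 4.0, 1.0, 1.0),    # full rate at the end of the zone
        (0.5, 1.0, 1.0, 1.0, 1.0),    # r = 1 flattens the ramp
        (2.0, 0.7, 4.0, 1.0, 0.7),    # GDP lattice beyond the zone
        (0.5, 0.8, 4.0, 0.0, 0.8),    # leading side: l = 0, constant rate
    ])
    def test_piecewise_values(self, x, lam, r, l, expected):
        assert np.isclose(hg.binding_profile(x, lam, r, l), expected)

    @given(lam=st.floats(0.01, 5), r=st.floats(1.0, 20), l=st.floats(0.1, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nondecreasing_in_x_when_r_above_one(self, lam, r, l):
        x = np.linspace(0, 4, 200)
        prof = hg.binding_profile(x, lam, r, l)
        assert np.all(np.diff(prof) >= -1e-12)

    def test_zero_ratio_rejected(self):
        with pytest.raises(InvalidParameterError):
            hg.binding_profile(1.0, 1.0, 0.0, 1.0)


class TestSimulate:
    def test_zero_rhs_keeps_initial_state(self, coarse_grid):
        p = hg.ModelParameters(D=0, lam=0, mu=0, v_plus=0, v_minus=0,
                               gamma1=0, gamma2=0)
        init = np.abs(np.sin(coarse_grid.x)) + 0.2
        run = hg.simulate(p, coarse_grid, init, 20.0, 5.0, "trailing")
        assert np.allclose(run.H, init[None, :], atol=1e-12)

    def test_reaction_only_relaxes_to_lam_over_mu(self, coarse_grid):
        p = hg.ModelParameters(D=0, lam=0.2, mu=0.1, v_plus=0, v_minus=0,
                               gamma1=0, gamma2=0, s=1e6, l=0)
        run = hg.simulate(p, coarse_grid, np.zeros(coarse_grid.n_cells),
                          200.0, 50.0, "trailing")
        target = 2.0 * hg.ran_gradient(coarse_grid.x, p.s)
        assert np.allclose(run.final, target, rtol=1e-6)

    def test_pure_diffusion_matches_heat_kernel(self):
        # Gaussian initial condition spreads with variance s0^2 + 2 D t
        L, D, s0, t = 6.0, 0.02, 0.3, 10.0
        grid = hg.SpatialGrid(L=L, n_cells=300)
        p = hg.ModelParameters(D=D, lam=0, mu=0, v_plus=0, v_minus=0,
                               gamma1=0, gamma2=0, L=L)
        init = np.exp(-0.5 * ((grid.x - L / 2) / s0) ** 2)
        run = hg.simulate(p, grid, init, t, t, "trailing")
        var = s0 ** 2 + 2 * D * t
        exact = s0 / np.sqrt(var) * np.exp(-0.5 * (grid.x - L / 2) ** 2 / var)
        err = np.max(np.abs(run.final - exact))
        assert err < 0.01 * exact.max()

    def test_heat_kernel_error_shrinks_under_refinement(self):
        L, D, s0, t = 6.0, 0.02, 0.3, 10.0
        errs = []
        for n in (100, 200, 400):
            grid = hg.SpatialGrid(L=L, n_cells=n)
            p = hg.ModelParameters(D=D, lam=0, mu=0, v_plus=0, v_minus=0,
                                   gamma1=0, gamma2=0, L=L)
            init = np.exp(-0.5 * ((grid.x - L / 2) / s0) ** 2)
            run = hg.simulate(p, grid, init, t, t, "trailing")
            var = s0 ** 2 + 2 * D * t
            exact = s0 / np.sqrt(var) * np.exp(
                -0.5 * (grid.x - L / 2) ** 2 / var)
            errs.append(np.max(np.abs(run.final - exact)))
        assert errs[0] > errs[1] > errs[2]

    def test_mass_conserved_with_reflecting_walls(self, default_grid):
        p = hg.ModelParameters(D=0.05, lam=0, mu=0, v_plus=0, v_minus=0,
                               gamma1=0, gamma2=0)
        init = np.exp(-((default_grid.x - 1.5) / 0.4) ** 2)
        run = hg.simulate(p, default_grid, init, 100.0, 100.0, "trailing")
        m0 = init.sum() * default_grid.dx
        m1 = run.final.sum() * default_grid.dx
        assert abs(m1 - m0) / m0 < 1e-6

    def test_advection_pulse_translates_at_speed_v(self):
        # periodic harness: pure transport, peak moves by v * t
        grid = hg.SpatialGrid(L=3.0, n_cells=300)
        v = 0.05
        p = hg.ModelParameters(D=0, lam=0, mu=0, v_plus=v, v_minus=0,
                               gamma1=0, gamma2=0)
        init = np.exp(-0.5 * ((grid.x - 1.0) / 0.2) ** 2)
        run = hg.simulate(p, grid, init, 10.0, 10.0, "trailing",
                          boundary="periodic")
        x_peak = grid.x[np.argmax(run.final)]
        assert abs(x_peak - (1.0 + v * 10.0)) < grid.dx

    def test_solution_nonnegative_at_defaults(self, truth, coarse_grid):
        run = hg.simulate(truth, coarse_grid,
                          np.zeros(coarse_grid.n_cells), 60.0, 4.1, "trailing")
        assert run.H.min() >= 0.0

    def test_boundary_interaction_monotone_in_gamma(self, coarse_grid):
        # stronger kinetochore interaction drives H(0) down at fixed time
        init = np.exp(-0.5 * ((coarse_grid.x - 1.5) / 0.4) ** 2)
        h0 = []
        for g1 in (0.0, 0.01, 0.1, 1.0, 10.0):
            p = hg.ModelParameters(D=0.05, lam=0, mu=0, v_plus=0, v_minus=0,
                                   gamma1=g1, gamma2=0)
            run = hg.simulate(p, coarse_grid, init, 30.0, 30.0, "trailing")
            h0.append(run.final[0])
        assert np.all(np.diff(h0) < 0)
        # gamma = 0 is the no-flux limit: mass conserved
        p0 = hg.ModelParameters(D=0.05, lam=0, mu=0, v_plus=0, v_minus=0,
                                gamma1=0, gamma2=0)
        run0 = hg.simulate(p0, coarse_grid, init, 30.0, 30.0, "trailing")
        assert np.isclose(run0.final.sum(), init.sum(), rtol=1e-9)


class TestEquilibrium:
    def test_no_source_gives_zero(self, truth, coarse_grid):
        eq = hg.equilibrium_profile(truth.replace(lam=0), coarse_grid,
                                    "trailing")
        assert np.allclose(eq, 0.0)

    def test_reaction_only_fixed_point(self, coarse_grid):
        p = hg.ModelParameters(D=0, v_plus=0, v_minus=0, lam=0.3, mu=0.12,
                               l=1.2, r=4.0, s=2.5, gamma1=0.02, gamma2=0.02)
        eq = hg.equilibrium_profile(p, coarse_grid, "trailing")
        expected = (hg.binding_profile(coarse_grid.x, p.lam, p.r, p.l)
                    * hg.ran_gradient(coarse_grid.x, p.s) / p.mu)
        assert np.allclose(eq, expected, rtol=1e-6)

    def test_sides_agree_when_zone_and_advection_vanish(self, coarse_grid):
        p = hg.ModelParameters(r=1.0, v_plus=0.0, v_minus=0.0)
        eq_trail = hg.equilibrium_profile(p, coarse_grid, "trailing")
        eq_lead = hg.equilibrium_profile(p, coarse_grid, "leading")
        assert np.allclose(eq_trail, eq_lead, rtol=1e-9)

    def test_nonconvergence_raises_with_residual(self, coarse_grid):
        p = hg.ModelParameters(mu=1e-4, lam=0.1, D=0, v_plus=0, v_minus=0,
                               gamma1=0, gamma2=0)
        with pytest.raises(ConvergenceError) as exc:
            hg.equilibrium_profile(p, coarse_grid, "trailing", tol=1e-12,
                                   max_time=50.0)
        assert exc.value.residual is not None


class TestAlternatingRun:
    def test_leading_initial_is_trailing_equilibrium(self, truth, coarse_grid):
        eq = hg.equilibrium_profile(truth, coarse_grid, "trailing")
        lead, trail = hg.alternating_run(truth, coarse_grid, 30.0, 30.0, 5.0)
        assert np.allclose(lead.H[0], eq)
        assert np.allclose(trail.H[0], lead.final)

    def test_sides_identical_without_zone_or_advection(self, coarse_grid):
        p = hg.ModelParameters(l=0.0, v_plus=0.0, v_minus=0.0)
        lead, trail = hg.alternating_run(p, coarse_grid, 30.0, 30.0, 5.0)
        # runs agree to the equilibrium-detection tolerance
        assert np.allclose(lead.H, trail.H, rtol=1e-4)

    def test_trailing_side_relaxes_monotonically_to_equilibrium(
            self, truth, coarse_grid):
        # after the switch the near-kinetochore signal moves monotonically
        # toward the trailing equilibrium value
        eq = hg.equilibrium_profile(truth, coarse_grid, "trailing")
        _, trail = hg.alternating_run(truth, coarse_grid, 60.0, 120.0, 10.0)
        k = slice(0, 5)  # near-kinetochore cells
        dist = np.abs(trail.H[:, k].mean(axis=1) - eq[k].mean())
        assert dist[-1] < 0.05 * dist[0] + 1e-9
        assert np.all(np.diff(dist) <= 1e-9)


class TestMeasureGap:
    def test_step_profile_crossing(self):
        # step at a cell face: 0 below 1.2 um, 10 above (dx = 0.1)
        grid = hg.SpatialGrid(L=3.0, n_cells=30)
        prof = np.where(grid.x < 1.2, 0.0, 10.0)
        assert np.isclose(hg.measure_gap(prof, grid.x, frac=0.5), 1.2)

    def test_uniform_profile_has_no_gap(self):
        grid = hg.SpatialGrid(L=3.0, n_cells=30)
        assert hg.measure_gap(np.full(30, 2.0), grid.x, frac=0.5) == 0.0

    def test_linear_ramp_half_maximum(self):
        grid = hg.SpatialGrid(L=3.0, n_cells=300)
        prof = 10.0 * grid.x / 3.0
        # half of the ramp maximum is reached at the ramp midpoint
        assert np.isclose(hg.measure_gap(prof, grid.x, frac=0.5), 1.5,
                          atol=grid.dx)

    def test_all_zero_profile_rejected(self):
        grid = hg.SpatialGrid(L=3.0, n_cells=30)
        with pytest.raises(UndefinedGapError):
            hg.measure_gap(np.zeros(30), grid.x)

    def test_gap_monotone_in_zone_length_and_speed(self, gap_base):
        # trailing steady states: gap grows with the excluded zone and
        # with the polymerisation speed
        grid = hg.SpatialGrid(L=3.0, n_cells=150)
        gaps = []
        for l in (0.0, 0.8, 1.6, 2.4):
            eq = hg.equilibrium_profile(gap_base.replace(l=l), grid,
                                        "trailing")
            gaps.append(hg.measure_gap(eq, grid.x))
        assert np.all(np.diff(gaps) >= 0)
        eq1 = hg.equilibrium_profile(gap_base, grid, "trailing")
        eq2 = hg.equilibrium_profile(gap_base.replace(v_plus=2 * gap_base.v_plus),
                                     grid, "trailing")
        assert hg.measure_gap(eq2, grid.x) >= hg.measure_gap(eq1, grid.x)


class TestDomainTypes:
    def test_grid_is_cell_centred(self):
        grid = hg.SpatialGrid(L=3.0, n_cells=300)
        assert np.isclose(grid.x[0], grid.dx / 2)
        assert np.isclose(grid.x[-1], grid.L - grid.dx / 2)
        assert np.allclose(np.diff(grid.x), grid.dx)
        assert np.isclose(grid.n_cells * grid.dx, grid.L)

    def test_profile_shape_and_negativity_guards(self, coarse_grid):
        times = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            hg.HurpProfile(grid=coarse_grid, times=times,
                           H=np.zeros((3, coarse_grid.n_cells)),
                           side="trailing")
        with pytest.raises(ValueError):
            hg.HurpProfile(grid=coarse_grid, times=times,
                           H=np.full((2, coarse_grid.n_cells), -1.0),
                           side="trailing")

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            hg.ModelParameters(l=4.0, L=3.0)
        with pytest.raises(ValueError):
            hg.ModelParameters(r=0.0)
        with pytest.raises(ValueError):
            hg.ModelParameters(D=-0.1)

    def test_operator_is_metzler(self, truth, coarse_grid):
        # positivity preservation rests on non-negative off-diagonals
        for side in ("leading", "trailing"):
            A, b = build_operator(truth, coarse_grid, side)
            off = A - np.diag(np.diag(A))
            assert off.min() >= 0
            assert b.min() >= 0
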