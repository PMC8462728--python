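"""Forward solvers: grid arithmetic, conservation, positivity, CFL, and the
discrete (monomer-resolved) companion model."""

import numpy as np
import pytest

import purefrag as pf
from purefrag.solver import GridSetupError


# ----------------------------------------------------------------------
class TestLogGrid:
    def test_pivot_lands_on_one(self):
        grid = pf.LogGrid.from_bounds(1e-4, 1e3, 600)
        assert grid.w[grid.pivot] == 0.0
        assert grid.x[grid.pivot] == pytest.approx(1.0)

    def test_uniform_spacing_and_index_arithmetic(self):
        grid = pf.LogGrid.from_bounds(1e-3, 50, 200)
        dw = np.diff(grid.w)
        assert np.allclose(dw, grid.delta_w)
        p = grid.pivot
        i, j = p + 3, p + 7  # keep i + j - p on the grid
        assert grid.w[i] + grid.w[j] == pytest.approx(grid.w[i + j - p])

    def test_dirac_grid_snaps_log2(self):
        grid = pf.LogGrid.for_dirac(1e-4, 1e3, 600)
        ratio = np.log(2.0) / grid.delta_w
        assert ratio == pytest.approx(round(ratio), abs=1e-12)

    def test_pivot_must_be_interior(self):
        with pytest.raises(GridSetupError):
            pf.LogGrid.from_bounds(2.0, 50.0, 100)


# ----------------------------------------------------------------------
class TestContinuousSolver:
    def test_initial_snapshot_reproduces_u0(self, exp_u0, uniform_kernel, small_grid):
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.0), uniform_kernel, exp_u0, grid=small_grid,
            t_final=0.5, output_times=[0.5],
        )
        assert np.allclose(res.u(0), exp_u0(res.x), rtol=1e-12)

    def test_mass_conserved_to_machine_precision(self, exp_u0, gaussian_kernel, small_grid):
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.5), gaussian_kernel, exp_u0, grid=small_grid,
            t_final=3.0, output_times=[0.5, 1.0, 3.0],
        )
        m0 = res.mass(0)
        for k in range(len(res.times)):
            assert abs(res.mass(k) - m0) / m0 <= 1e-12

    def test_positivity_even_with_large_dt(self, exp_u0, uniform_kernel, small_grid):
        """The implicit scheme keeps n >= 0 for any time step."""
        res = pf.solve_continuous(
            pf.FragmentationParameters(2.0), uniform_kernel, exp_u0, grid=small_grid,
            delta_t=0.5, t_final=5.0, output_times=[5.0],
        )
        assert np.all(res.n_values >= 0)

    def test_particle_number_nondecreasing(self, exp_u0, uniform_kernel, small_grid):
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.0), uniform_kernel, exp_u0, grid=small_grid,
            t_final=4.0, output_times=[1.0, 2.0, 4.0],
        )
        numbers = [res.number(k) for k in range(len(res.times))]
        assert all(b >= a * (1 - 1e-12) for a, b in zip(numbers[:-1], numbers[1:]))

    def test_snapshots_hit_requested_times(self, exp_u0, uniform_kernel, small_grid):
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.0), uniform_kernel, exp_u0, grid=small_grid,
            delta_t=0.013, t_final=1.0, output_times=[0.25, 0.7, 1.0],
        )
        assert np.allclose(res.times, [0.0, 0.25, 0.7, 1.0])

    def test_narrow_grid_rejected(self, uniform_kernel):
        narrow = pf.LogGrid.from_bounds(0.5, 2.0, 50)
        with pytest.raises(GridSetupError):
            pf.solve_continuous(
                pf.FragmentationParameters(1.0), uniform_kernel,
                lambda x: np.exp(-np.asarray(x, float)), grid=narrow, t_final=0.1,
            )

    def test_dirac_kernel_needs_snapped_grid(self, exp_u0):
        kern = pf.make_kernel("dirac_half")
        bad = pf.LogGrid.from_bounds(1e-3, 17.3, 301)
        ratio = np.log(2) / bad.delta_w
        assert abs(ratio - round(ratio)) > 1e-9  # genuinely non-snapped
        with pytest.raises(GridSetupError):
            pf.solve_continuous(
                pf.FragmentationParameters(1.0), kern, exp_u0, grid=bad, t_final=0.1
            )


# ----------------------------------------------------------------------
class TestExplicitScheme:
    def test_cfl_violation_refused_with_bound(self, exp_u0, uniform_kernel, small_grid):
        bound = 1.0 / np.exp(small_grid.w[-1])
        with pytest.raises(pf.CFLError) as err:
            pf.solve_continuous_explicit(
                pf.FragmentationParameters(1.0), uniform_kernel, exp_u0,
                grid=small_grid, delta_t=bound * 10,
            )
        assert f"{bound:g}" in str(err.value)

    def test_matches_implicit_scheme(self, exp_u0, uniform_kernel, small_grid):
        """Both schemes converge to the same solution; at small shared dt
        their difference is O(dt)."""
        kw = dict(grid=small_grid, delta_t=1e-3, t_final=1.0, output_times=[1.0])
        p = pf.FragmentationParameters(1.0)
        ri = pf.solve_continuous(p, uniform_kernel, exp_u0, **kw)
        re = pf.solve_continuous_explicit(p, uniform_kernel, exp_u0, **kw)
        num = np.trapezoid(np.abs(ri.u(1) - re.u(1)), small_grid.x)
        den = np.trapezoid(ri.u(1), small_grid.x)
        assert num / den < 5e-3

    def test_initial_snapshot(self, exp_u0, uniform_kernel, small_grid):
        re = pf.solve_continuous_explicit(
            pf.FragmentationParameters(1.0), uniform_kernel, exp_u0,
            grid=small_grid, t_final=0.05, output_times=[0.05],
        )
        assert np.allclose(re.u(0), exp_u0(re.x), rtol=1e-12)


# ----------------------------------------------------------------------
class TestDiscreteModel:
    def test_monomer_mass_conserved_and_number_grows(self, uniform_kernel):
        N, r = 400, 1.0 / 200
        counts0 = np.exp(-np.arange(N + 1) * r)
        counts0[0] = 0.0
        ds = pf.solve_discrete(
            pf.FragmentationParameters(1.0), uniform_kernel, r, counts0, N, t_final=1.0,
            output_times=[0.5, 1.0],
        )
        for k in range(len(ds.times)):
            assert ds.monomer_mass(k) == pytest.approx(ds.monomer_mass(0), rel=1e-9)
        nums = [ds.total_number(k) for k in range(len(ds.times))]
        assert nums[0] < nums[1] < nums[2]

    def test_monodisperse_number_growth_dirac(self):
        """A monodisperse population under half-splitting only gains
        particles."""
        kern = pf.make_kernel("dirac_half")
        N = 128
        counts0 = np.zeros(N + 1)
        counts0[N] = 1000.0
        ds = pf.solve_discrete(
            pf.FragmentationParameters(0.2), kern, 1.0 / 64, counts0, N, t_final=2.0,
            output_times=[1.0, 2.0],
        )
        nums = [ds.total_number(k) for k in range(3)]
        assert nums[0] < nums[1] < nums[2]
        assert ds.monomer_mass(2) == pytest.approx(ds.monomer_mass(0), rel=1e-9)

    def test_matches_continuous_model(self, uniform_kernel):
        """The paper-style cross-validation: N = 2000 monomers of length
        1/1000, gamma = 1, uniform kernel; binned length distributions of the
        two codes agree to a few percent."""
        N, r = 2000, 1.0 / 1000
        ell = np.arange(N + 1)
        counts0 = np.exp(-ell * r)
        counts0[0] = 0.0
        ds = pf.solve_discrete(
            pf.FragmentationParameters(1.0), uniform_kernel, r, counts0, N, t_final=1.0,
            output_times=[1.0],
        )

        def u0(x):
            x = np.asarray(x, dtype=float)
            return np.where(x <= N * r, np.exp(-x), 0.0)

        grid = pf.LogGrid.from_bounds(1e-3, 2.5, 500)
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.0), uniform_kernel, u0, grid=grid,
            t_final=1.0, output_times=[1.0], check_mass=False,
        )
        fc = pf.normalize(res.x, res.u(res.index_of_time(1.0)))
        L, pmf = ds.length_distribution(1)
        from scipy.integrate import cumulative_trapezoid

        cdfc = cumulative_trapezoid(fc.f, fc.x, initial=0.0)
        cdfc /= cdfc[-1]
        edges = np.linspace(0.0, N * r, 41)
        pc = np.diff(np.interp(edges, fc.x, cdfc))
        pd_ = np.diff(np.interp(edges, L, np.cumsum(pmf)))
        assert np.abs(pc - pd_).sum() <= 0.05
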