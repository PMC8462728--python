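"""Normalization, moments, self-similar rescaling, Mellin transforms,
the steady-moment recursion, and profile-shape classification."""

import numpy as np
import pytest
from scipy import special

import purefrag as pf
from purefrag.observables import ResonanceError


@pytest.fixture(scope="module")
def xgrid():
    return np.geomspace(1e-5, 60.0, 3000)


class TestNormalizeAndMoments:
    def test_unit_mass_and_scale_invariance(self, xgrid):
        f1 = pf.normalize(xgrid, np.exp(-xgrid))
        f5 = pf.normalize(xgrid, 5.0 * np.exp(-xgrid))
        assert f1.integral() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(f1.f, f5.f)

    def test_zero_mass_rejected(self, xgrid):
        with pytest.raises(ValueError):
            pf.normalize(xgrid, np.zeros_like(xgrid))

    def test_gamma_function_moments(self, xgrid):
        f = pf.normalize(xgrid, np.exp(-xgrid))
        assert pf.moment(f, 0.0) == pytest.approx(1.0, abs=1e-8)
        assert pf.moment(f, 1.0) == pytest.approx(1.0, rel=1e-4)
        assert pf.moment(f, 2.0) == pytest.approx(2.0, rel=1e-4)

    def test_sample_moment_is_mean_of_powers(self):
        sample = np.array([1.0, 2.0, 3.0])
        assert pf.moment(sample, 2.0) == pytest.approx(np.mean(sample**2))
        with pytest.raises(ValueError):
            pf.moment(np.array([]), 1.0)

    def test_oracle_trajectory_moment(self, xgrid):
        u = pf.oracle_solution("uniform_anyg_exp_init", 3.0, xgrid, gamma=1.0, s=1.0)
        f = pf.normalize(xgrid, np.asarray(u, float), time=3.0)
        assert f.moment(1.0) == pytest.approx(0.25, rel=1e-4)


class TestRescaling:
    def test_identity_at_t_equal_one(self, xgrid):
        d = pf.normalize(xgrid, np.exp(-xgrid), time=1.0)
        prof = pf.rescaled_profile(d, gamma=1.0)
        assert np.allclose(prof.g, d.f, rtol=1e-10)

    def test_oracle_rescales_to_exponential(self, xgrid):
        """gamma = 1 uniform-kernel trajectory at t = 100 rescales onto
        e^{-x} within 2%."""
        t = 100.0
        u = np.exp(-(1.0 + t) * xgrid) * (1.0 + t) ** 2
        d = pf.normalize(xgrid, u, time=t)
        prof = pf.rescaled_profile(d, gamma=1.0)
        target = np.exp(-prof.x)
        target /= np.trapezoid(target, prof.x)
        sup = np.max(np.abs(prof.g - target)) / np.max(target)
        assert sup <= 0.02

    def test_two_late_times_agree(self, medium_grid, exp_u0, uniform_kernel):
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.0), uniform_kernel, exp_u0, grid=medium_grid,
            t_final=80.0, output_times=[40.0, 80.0],
        )
        profs = []
        xg = np.geomspace(1e-3, 30.0, 500)
        for t in [40.0, 80.0]:
            d = pf.normalize(res.x, res.u(res.index_of_time(t)), time=t)
            profs.append(pf.rescaled_profile(d, gamma=1.0, x_grid=xg))
        l1 = np.trapezoid(np.abs(profs[0].g - profs[1].g), xg)
        assert l1 <= 0.02

    def test_requires_positive_time(self, xgrid):
        d = pf.normalize(xgrid, np.exp(-xgrid), time=0.0)
        with pytest.raises(ValueError):
            pf.rescaled_profile(d, gamma=1.0)


class TestMellinNumeric:
    def test_gamma_integrals(self, exp_profile):
        assert complex(pf.mellin_numeric(exp_profile, 2.0)).real == pytest.approx(1.0, rel=1e-5)
        assert complex(pf.mellin_numeric(exp_profile, 1.0)).real == pytest.approx(1.0, rel=1e-6)

    def test_complex_argument_matches_gamma_function(self):
        x = np.geomspace(1e-6, 80.0, 12000)
        g = np.exp(-x)
        g /= np.trapezoid(g, x)
        prof = pf.SteadyProfile(x=x, g=g)
        s = 2.0 + 3.0j
        val = pf.mellin_numeric(prof, s)
        assert abs(val - special.gamma(s)) <= 1e-6

    def test_unresolved_tail_warns(self):
        x = np.geomspace(0.5, 5.0, 50)  # grid far too narrow
        g = np.exp(-x)
        g /= np.trapezoid(g, x)
        prof = pf.SteadyProfile(x=x, g=g)
        with pytest.warns(RuntimeWarning):
            pf.mellin_numeric(prof, 6.0)


class TestSteadyMomentRecursion:
    def test_uniform_gamma1_anchor(self, uniform_kernel):
        """G(2) = (2-1) G(1) / (1*1*(K(1)-1)) = 1: the mean of e^{-x}."""
        vals = pf.steady_moments_recursion(
            pf.FragmentationParameters(1.0), uniform_kernel, start_s=1.0, n_steps=1
        )
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == pytest.approx(1.0)

    def test_matches_long_simulation_gamma15(self, exp_u0, uniform_kernel):
        """Non-resonant chain 1 -> 2.5 -> 4 at gamma = 1.5 agrees with
        numeric Mellin transforms of a long run within 3%."""
        p = pf.FragmentationParameters(1.5)
        rec = pf.steady_moments_recursion(p, uniform_kernel, start_s=1.0, n_steps=2)
        assert rec[1] == pytest.approx(2.0 / 3.0)
        grid = pf.LogGrid.from_bounds(1e-5, 30.0, 700)
        res = pf.solve_continuous(
            p, uniform_kernel, exp_u0, grid=grid, t_final=200.0, output_times=[200.0]
        )
        d = pf.normalize(res.x, res.u(res.index_of_time(200.0)), time=200.0)
        prof = pf.rescaled_profile(d, gamma=1.5)
        for k, s in [(1, 2.5), (2, 4.0)]:
            sim = complex(pf.mellin_numeric(prof, s)).real
            assert sim == pytest.approx(float(rec[k]), rel=0.03)

    def test_resonance_at_s2_raises(self, uniform_kernel):
        with pytest.raises(ResonanceError):
            pf.steady_moments_recursion(
                pf.FragmentationParameters(1.0), uniform_kernel, start_s=2.0, n_steps=1
            )


class TestProfileClassification:
    def test_exponential_profile_is_class_b(self, xgrid):
        g = np.exp(-xgrid)
        g /= np.trapezoid(g, xgrid)
        assert pf.classify_profile(pf.SteadyProfile(x=xgrid, g=g)) == "B"

    def test_unimodal_vanishing_profile_is_class_a(self, xgrid):
        g = xgrid * np.exp(-xgrid)
        g /= np.trapezoid(g, xgrid)
        assert pf.classify_profile(pf.SteadyProfile(x=xgrid, g=g)) == "A"

    def test_simulated_gaussian_kernel_profile_is_class_a(
        self, medium_grid, exp_u0, gaussian_kernel
    ):
        res = pf.solve_continuous(
            pf.FragmentationParameters(1.0), gaussian_kernel, exp_u0, grid=medium_grid,
            t_final=60.0, output_times=[60.0],
        )
        d = pf.normalize(res.x, res.u(res.index_of_time(60.0)), time=60.0)
        prof = pf.rescaled_profile(d, gamma=1.0)
        assert pf.classify_profile(prof) == "A"


class TestScalingLaws:
    def test_alpha_is_a_time_scaling(self, small_grid, exp_u0, gaussian_kernel):
        """Doubling alpha halves the clock: u_2(t) = u_1(2t) for the same
        initial data, and the literal 1/alpha form holds once the initial
        data are scaled accordingly (the equation is linear)."""
        k = gaussian_kernel
        r1 = pf.solve_continuous(
            pf.FragmentationParameters(1.0, 1.0), k, exp_u0, grid=small_grid,
            delta_t=0.005, t_final=10.0, output_times=[10.0],
        )
        r2 = pf.solve_continuous(
            pf.FragmentationParameters(1.0, 2.0), k, exp_u0, grid=small_grid,
            delta_t=0.0025, t_final=5.0, output_times=[5.0],
        )
        ua = r2.u(r2.index_of_time(5.0))
        ub = r1.u(r1.index_of_time(10.0))
        rel = np.trapezoid(np.abs(ua - ub), small_grid.x) / np.trapezoid(ub, small_grid.x)
        assert rel <= 0.01
        # literal form with the 1/alpha-scaled initial data: by linearity it
        # is exactly half of the same-discretization alpha = 2 run
        half = pf.solve_continuous(
            pf.FragmentationParameters(1.0, 2.0), k,
            lambda x: 0.5 * exp_u0(x), grid=small_grid, delta_t=0.0025,
            t_final=5.0, output_times=[5.0],
        )
        assert np.allclose(half.u(1), 0.5 * ua, rtol=1e-9, atol=1e-15)

    def test_rescaled_profiles_related_by_alpha_map(self, small_grid, exp_u0, gaussian_kernel):
        """g_alpha(y) = alpha^{1/gamma} g_hat(alpha^{1/gamma} y) for
        unit-mass profiles (gamma = 1, alpha = 2)."""
        k = gaussian_kernel
        r1 = pf.solve_continuous(
            pf.FragmentationParameters(1.0, 1.0), k, exp_u0, grid=small_grid,
            t_final=100.0, output_times=[100.0],
        )
        r2 = pf.solve_continuous(
            pf.FragmentationParameters(1.0, 2.0), k, exp_u0, grid=small_grid,
            t_final=50.0, output_times=[50.0],
        )
        xg = np.geomspace(1e-3, 10.0, 400)
        p1 = pf.rescaled_profile(
            pf.normalize(r1.x, r1.u(1), time=100.0), gamma=1.0, x_grid=2.0 * xg
        )
        p2 = pf.rescaled_profile(pf.normalize(r2.x, r2.u(1), time=50.0), gamma=1.0, x_grid=xg)
        mapped = 2.0 * p1.g  # alpha^{1/gamma} g(alpha^{1/gamma} y)
        l1 = np.trapezoid(np.abs(p2.g - mapped), xg)
        assert l1 <= 0.02

    def test_profile_tail_is_stretched_exponential(
        self, medium_grid, exp_u0, uniform_kernel
    ):
        """log g_hat(x) ~ const - x^gamma at large x.

        Under the rescaling t^{-2/gamma} u(t, t^{-1/gamma} x), the exact
        gamma = 2 closed form tends to 2 e^{-x^2}, fixing the exponent
        normalization; the simulated gamma = 1.5 tail must match it."""
        gam = 1.5
        res = pf.solve_continuous(
            pf.FragmentationParameters(gam), uniform_kernel, exp_u0, grid=medium_grid,
            t_final=100.0, output_times=[100.0],
        )
        d = pf.normalize(res.x, res.u(1), time=100.0)
        prof = pf.rescaled_profile(d, gamma=gam)
        mask = (prof.x > 2.0) & (prof.g > 1e-12)
        slope = np.polyfit(prof.x[mask] ** gam, np.log(prof.g[mask]), 1)[0]
        assert slope == pytest.approx(-1.0, rel=0.15)
        # and the exact gamma = 2 oracle confirms the normalization
        t = 400.0
        x = np.geomspace(1e-4, 50.0, 3000)
        u = pf.oracle_solution("uniform_g2_exp_init", t, x)
        prof2 = pf.rescaled_profile(pf.normalize(x, np.asarray(u, float), time=t), gamma=2.0)
        m2 = (prof2.x > 1.0) & (prof2.x < 4.0) & (prof2.g > 0)
        slope2 = np.polyfit(prof2.x[m2] ** 2, np.log(prof2.g[m2]), 1)[0]
        assert slope2 == pytest.approx(-1.0, rel=0.05)

    def test_small_z_kernel_exponent_transfers_to_profile(
        self, medium_grid, exp_u0, uniform_kernel
    ):
        """kappa ~ C z^eps near 0 implies g_hat ~ C' x^eps: eps = 0 for the
        uniform kernel (flat log-log slope near 0), eps = 1 for the
        parabolic kernel, within 20%."""
        for kern, eps in [(uniform_kernel, 0.0), (pf.make_kernel("parabolic"), 1.0)]:
            res = pf.solve_continuous(
                pf.FragmentationParameters(1.0), kern, exp_u0, grid=medium_grid,
                t_final=60.0, output_times=[60.0],
            )
            d = pf.normalize(res.x, res.u(1), time=60.0)
            prof = pf.rescaled_profile(d, gamma=1.0)
            x_char = prof.moment(1.0)
            mask = (prof.x > 5e-3 * x_char) & (prof.x < 5e-2 * x_char) & (prof.g > 0)
            slope = np.polyfit(np.log(prof.x[mask]), np.log(prof.g[mask]), 1)[0]
            assert abs(slope - eps) <= 0.2
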