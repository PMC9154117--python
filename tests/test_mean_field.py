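"""Mean-field ODE engine: right-hand side, fixed points, stability, timing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import foragesim as fs
from foragesim import mean_field as mf
from foragesim.mean_field import MeanFieldState
from foragesim.model_core import assemble_system


def _random_system(rng):
    n = rng.integers(2, 5)
    env = fs.make_environment(rng.uniform(0.1, 1.0, n))
    a = 10.0 ** rng.uniform(-4, -2)
    rho = 10.0 ** rng.uniform(1, 3)
    variant = rng.choice(["positive_only", "negative_feedback", "asocial"])
    z = float(a * rho * rng.uniform(0.5, 20)) if variant == "negative_feedback" else 0.0
    r = rho * env.qualities.mean() if variant == "negative_feedback" else rho
    if variant == "asocial":
        return fs.build_system(variant, env, a=a, r=1.0)
    return fs.build_system(variant, env, a=a, r=r, z=z, rho=rho)


class TestRhs:
    @pytest.mark.parametrize("variant,z", [("positive_only", 0.0),
                                           ("negative_feedback", 3.1),
                                           ("asocial", 0.0)])
    def test_fully_uncommitted_rate_is_discovery_only(self, canonical_env, variant, z):
        system = fs.build_system(variant, canonical_env, a=1e-3, r=100.0, z=z)
        np.testing.assert_allclose(
            mf.ode_rhs(mf.fully_uncommitted(3), system), canonical_env.qualities
        )

    def test_hand_evaluated_mass_action_terms(self):
        # q=(0.75,0.5), rho=100, a=1e-3 at x=(0.4,0.3):
        # dx1 = 0.75*0.3 - 0.001*0.4 + 100*0.3*0.4 = 12.2246
        # dx2 = 0.50*0.3 - 0.001*0.3 + 100*0.3*0.3 =  9.1497
        env = fs.make_environment([0.75, 0.5])
        system = fs.build_system("positive_only", env, a=1e-3, r=100.0)
        np.testing.assert_allclose(
            mf.ode_rhs(np.array([0.4, 0.3]), system), [12.2246, 9.1497]
        )

    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_reaction_by_reaction_mass_action_sum(self, seed):
        rng = np.random.default_rng(seed)
        system = _random_system(rng)
        x = rng.dirichlet(np.ones(system.n + 1))[1:]
        np.testing.assert_allclose(
            mf.ode_rhs(x, system),
            mf.rhs_from_reactions(x, system),
            rtol=1e-12, atol=1e-12,
        )

    def test_rhs_vanishes_at_reported_fixed_point(self, neg_system):
        fp = mf.find_fixed_point(neg_system).fixed_point
        assert np.max(np.abs(mf.ode_rhs(fp, neg_system))) < 1e-10


class TestIntegrate:
    def test_asocial_single_patch_matches_linear_closed_form(self):
        env = fs.make_environment([1.0])
        system = fs.build_system("asocial", env, a=1e-3, r=1.0)
        q, a = 1.0, 1e-3
        times = np.linspace(0.1, 10.0, 40)
        traj = mf.integrate(system, t_end=10.0, t_eval=times)
        expected = (q / (q + a)) * (1.0 - np.exp(-(q + a) * times))
        np.testing.assert_allclose(traj.x[:, 0], expected, rtol=1e-7, atol=1e-10)

    def test_canonical_negative_feedback_reaches_target_ball(
        self, neg_system, canonical_target
    ):
        traj = mf.integrate(neg_system, t_end=400.0, t_eval=np.array([400.0]))
        assert fs.r2_error(traj.x[-1], canonical_target) < 1e-4

    def test_starting_at_fixed_point_stays_there(self, asocial_system):
        fp = mf.find_fixed_point(asocial_system).fixed_point
        traj = mf.integrate(asocial_system, fp, t_end=50.0,
                            t_eval=np.linspace(1, 50, 10))
        np.testing.assert_allclose(traj.x, np.tile(fp.x, (10, 1)), atol=1e-9)

    @given(seed=st.integers(0, 10_000))
    def test_simplex_conservation_and_nonnegativity_along_trajectory(self, seed):
        rng = np.random.default_rng(seed)
        system = _random_system(rng)
        traj = mf.integrate(system, t_end=50.0)
        assert traj.x.min() >= -1e-9
        assert np.max(traj.x.sum(axis=1)) <= 1.0 + 1e-9
        assert np.max(np.abs(traj.x_U + traj.x.sum(axis=1) - 1.0)) < 1e-9

    def test_invalid_arguments_rejected(self, neg_system):
        with pytest.raises(ValueError):
            mf.integrate(neg_system, t_end=-1.0)
        with pytest.raises(ValueError):
            mf.integrate(neg_system, t_end=1.0, rel_tol=0.0)


class TestFixedPoints:
    def test_positive_only_closed_form_example(self):
        env = fs.make_environment([0.75, 0.5])
        system = fs.build_system("positive_only", env, a=1e-3, r=100.0)
        report = mf.find_fixed_point(system)
        assert report.fixed_point.x_U == pytest.approx(9.8765e-6, rel=1e-3)
        # committed fractions exactly proportional to q
        x = report.fixed_point.x
        assert abs(x[0] * 0.5 - x[1] * 0.75) < 1e-12
        assert report.stable

    @pytest.mark.parametrize("variant", ["positive_only", "negative_feedback", "asocial"])
    def test_equal_qualities_give_symmetric_fixed_point(self, variant):
        env = fs.make_environment([0.4, 0.4, 0.4])
        z = 3.1 if variant == "negative_feedback" else 0.0
        system = fs.build_system(variant, env, a=1e-3, r=100.0, z=z)
        x = mf.find_fixed_point(system).fixed_point.x
        assert np.ptp(x) < 1e-10

    def test_exact_z_hits_target_allocation_exactly(self, canonical_env):
        system = fs.build_system("negative_feedback", canonical_env,
                                 a=1e-3, r=100.0, z=0.2)  # z = a*rho = 1e-3*200
        x = mf.find_fixed_point(system).fixed_point.x
        target = fs.target_distribution(canonical_env)
        assert fs.metrics.allocation_r2(x, target) < 1e-24
        np.testing.assert_allclose(
            x, canonical_env.qualities / (1e-3 + canonical_env.qualities.sum()),
            rtol=1e-10,
        )

    def test_error_grows_with_z_above_exactness_point(self, canonical_env,
                                                      canonical_target):
        r2s = []
        for z in [0.2, 0.8, 3.1, 12.0]:
            system = fs.build_system("negative_feedback", canonical_env,
                                     a=1e-3, r=100.0, z=z)
            x = mf.find_fixed_point(system).fixed_point.x
            r2s.append(fs.r2_error(x, canonical_target))
        assert np.all(np.diff(r2s) > 0)

    def test_canonical_negative_feedback_point_is_stable_and_near_target(
        self, neg_system, canonical_target
    ):
        report = mf.find_fixed_point(neg_system)
        assert report.stable
        r2 = fs.r2_error(report.fixed_point.x, canonical_target)
        assert 0.0 < r2 < 1e-3


class TestStability:
    def test_asocial_single_patch_eigenvalue(self):
        env = fs.make_environment([1.0])
        system = fs.build_system("asocial", env, a=1e-3, r=1.0)
        fp = mf.find_fixed_point(system).fixed_point
        eig = mf.stability_eigenvalues(system, fp)
        np.testing.assert_allclose(eig, [-1.001], rtol=1e-9)

    @given(seed=st.integers(0, 10_000))
    def test_analytic_jacobian_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        system = _random_system(rng)
        x = rng.dirichlet(np.ones(system.n + 1))[1:]
        h = 1e-7
        num = np.zeros((system.n, system.n))
        for j in range(system.n):
            e = np.zeros(system.n)
            e[j] = h
            num[:, j] = (mf.ode_rhs(x + e, system) - mf.ode_rhs(x - e, system)) / (2 * h)
        np.testing.assert_allclose(mf.ode_jacobian(x, system), num,
                                   rtol=1e-5, atol=1e-5)

    def test_rejects_non_fixed_point(self, neg_system):
        with pytest.raises(ValueError, match="not a fixed point"):
            mf.stability_eigenvalues(neg_system, np.array([0.3, 0.3, 0.3]))


class TestConvergenceTime:
    def test_zero_when_starting_inside_tolerance_ball(self, neg_system):
        fp = mf.find_fixed_point(neg_system).fixed_point
        assert mf.convergence_time(neg_system, fp, fp.x,
                                   check_fixed_point=False) == 0.0

    def test_decreases_along_increasing_z_grid(self, canonical_env):
        times = []
        for z in [0.5, 2.0, 8.0]:
            system = fs.build_system("negative_feedback", canonical_env,
                                     a=1e-3, r=100.0, z=z)
            fp = mf.find_fixed_point(system).fixed_point
            times.append(mf.convergence_time(system, None, fp.x,
                                             check_fixed_point=False))
        assert times[0] > times[1] > times[2]

    def test_unreachable_reference_is_an_error(self, neg_system):
        bad_ref = np.array([0.1, 0.1, 0.8])
        with pytest.raises(mf.ConvergenceError):
            mf.convergence_time(neg_system, None, bad_ref, tol=1e-6)

    def test_non_convergence_within_horizon_is_reported(self, pos_system,
                                                        canonical_target):
        perturbed = MeanFieldState(np.array([0.0, 0.0, 0.05]))
        with pytest.raises(mf.ConvergenceError, match="not converged"):
            mf.convergence_time(pos_system, perturbed, canonical_target,
                                max_horizon=100.0)
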