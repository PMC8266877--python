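"""Model assembly, the product equilibrium, simulation, and stability."""

import numpy as np
import pytest

import metapopgames as mg
from metapopgames.dispersal import NotDetailedBalancedError
from metapopgames.generators import GeneratorSpec, random_model
from metapopgames.models import NotCompletelyMixedError


class TestAssemble:
    def test_cycle_model_is_heterogeneous(self, heterogeneous_model):
        assert heterogeneous_model.homogeneity == "heterogeneous"
        np.testing.assert_allclose(heterogeneous_model.y_star, 1 / 3, atol=1e-12)
        np.testing.assert_allclose(heterogeneous_model.z_star, [0.2, 0.4, 0.4],
                                   atol=1e-12)

    def test_star_model_is_homogeneous(self, homogeneous_model):
        assert homogeneous_model.homogeneity == "homogeneous"
        np.testing.assert_allclose(homogeneous_model.kappas, 1 / 3, atol=1e-12)

    def test_rejects_even_species_count(self, cycle_graph):
        T = mg.validate_tournament([[0, 1], [-1, 0]])
        with pytest.raises(NotCompletelyMixedError) as exc:
            mg.assemble(T, cycle_graph)
        assert exc.value.certificate is not None

    def test_rejects_unbalanced_graph(self, unit_rps):
        G = mg.build_graph([(1, 2, 1.0, 2.0), (2, 3, 1.0, 2.0), (3, 1, 1.0, 2.0)])
        with pytest.raises(NotDetailedBalancedError) as exc:
            mg.assemble(unit_rps, G)
        assert exc.value.certificate.residual > 0.1


class TestCoexistenceEquilibrium:
    def test_cycle_model_printed_values(self, heterogeneous_model):
        xs = mg.coexistence_equilibrium(heterogeneous_model)
        np.testing.assert_allclose(xs[:, 0], 1 / 15, atol=1e-12)
        np.testing.assert_allclose(xs[:, 1:], 2 / 15, atol=1e-12)
        assert abs(xs.sum() - 1.0) < 1e-12

    def test_star_model_uniform_ninth(self, homogeneous_model):
        np.testing.assert_allclose(
            mg.coexistence_equilibrium(homogeneous_model), 1 / 9, atol=1e-12
        )

    def test_rhs_vanishes_at_equilibrium(self, heterogeneous_model, homogeneous_model):
        for model in (heterogeneous_model, homogeneous_model):
            xs = model.x_star
            assert np.abs(mg.full_rhs(model, xs)).max() < 1e-12

    def test_grand_total_one_on_random_models(self):
        for seed in range(5):
            model = random_model(GeneratorSpec(n=5, m=4, extra_edges=2, seed=seed))
            xs = mg.coexistence_equilibrium(model)
            assert abs(xs.sum() - 1.0) < 1e-12
            assert np.abs(mg.full_rhs(model, xs)).max() < 1e-12

    def test_uniqueness_probe_multistart(self, heterogeneous_model):
        # many interior starts all converge to the same root of the rhs
        from scipy.optimize import fsolve

        model = heterogeneous_model
        n, m = model.n, model.m
        rng = np.random.default_rng(1)
        found = []
        for _ in range(100):
            x0 = rng.dirichlet(np.ones(n * m)).reshape(n, m)
            sol = fsolve(lambda v: mg.full_rhs(model, v.reshape(n, m)).ravel()
                         + (v.sum() - 1.0),  # pin the conserved total
                         x0.ravel(), full_output=False, xtol=1e-12)
            x = sol.reshape(n, m)
            if np.all(x > 1e-6) and np.abs(mg.full_rhs(model, x)).max() < 1e-9:
                found.append(x)
        assert found, "no interior roots located"
        for x in found:
            np.testing.assert_allclose(x, model.x_star, atol=1e-6)


class TestFullRhs:
    def test_balanced_and_general_forms_agree(self, heterogeneous_model):
        model = heterogeneous_model
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.dirichlet(np.ones(model.n * model.m)).reshape(model.n, model.m)
            a = mg.full_rhs(model, x)
            b = mg.general_rhs(model.tournament, model.graph, x)
            np.testing.assert_allclose(a, b, atol=1e-12)
            assert abs(a.sum()) < 1e-13

    def test_boundary_derivative_nonnegative(self, heterogeneous_model):
        # an extinct-in-one-patch species can only (re)gain from migration:
        # if x[i,j] = 0 then dx[i,j]/dt = sum_k A[k,j] x[i,k] >= 0
        model = heterogeneous_model
        A = model.graph.adjacency
        rng = np.random.default_rng(4)
        x = rng.dirichlet(np.ones(model.n * model.m)).reshape(model.n, model.m)
        x[1, 2] = 0.0
        rhs = mg.general_rhs(model.tournament, model.graph, x)
        expected = sum(A[k, 2] * x[1, k] for k in range(model.m))
        assert rhs[1, 2] == pytest.approx(expected)
        assert rhs[1, 2] >= 0.0


class TestSimulate:
    def test_equilibrium_start_stays_put(self, heterogeneous_model):
        traj = mg.simulate(heterogeneous_model, heterogeneous_model.x_star,
                           t_end=10.0, n_samples=11)
        assert np.abs(traj.states - heterogeneous_model.x_star).max() < 1e-12

    def test_rejects_bad_starts(self, heterogeneous_model):
        xs = heterogeneous_model.x_star
        with pytest.raises(ValueError):
            mg.simulate(heterogeneous_model, 2 * xs, t_end=1.0)
        boundary = xs.copy()
        boundary[0, 0] = 0.0
        boundary[0, 1] += xs[0, 0]
        with pytest.raises(ValueError):
            mg.simulate(heterogeneous_model, boundary, t_end=1.0)

    def test_simplex_invariance_long_horizon(self):
        # grand total conserved to 1e-8 over t = 1000 on random models
        for seed in range(3):
            model = random_model(GeneratorSpec(seed=seed))
            x0 = mg.perturbed_initial_state(model.x_star, 0.1, seed=seed)
            traj = mg.simulate(model, x0, t_end=1000.0, n_samples=501)
            assert traj.diagnostics["grand_total_drift"] < 1e-8
            assert traj.states.min() > 0
            assert traj.states.max() < 1

    def test_homogeneous_synchronized_start_reduces_to_meanfield(
            self, homogeneous_model, unit_rps):
        # patch-synchronized columns follow the single-patch replicator flow
        # slowed by the factor m: on the synchronized manifold the species
        # totals obey dq_i/dt = (1/m) q_i (T q)_i
        model = homogeneous_model
        q0 = np.array([0.5, 0.3, 0.2])
        x0 = np.outer(q0, np.full(model.m, 1 / model.m))
        traj = mg.simulate(model, x0, t_end=50.0, n_samples=501)
        mf = mg.simulate_meanfield(unit_rps, q0, t_end=50.0 / model.m, n_samples=501)
        for j in range(model.m):
            patch_share = traj.states[:, :, j] * model.m
            np.testing.assert_allclose(patch_share, mf.states, atol=1e-6)


class TestLyapunov:
    def test_zero_at_equilibrium(self, heterogeneous_model):
        assert mg.lyapunov(heterogeneous_model, heterogeneous_model.x_star) == 0.0
        assert mg.lyapunov_rate(heterogeneous_model, heterogeneous_model.x_star) == \
            pytest.approx(0.0, abs=1e-15)

    def test_positive_away_from_equilibrium(self, heterogeneous_model):
        x = mg.perturbed_initial_state(heterogeneous_model.x_star, 0.3, seed=9)
        assert mg.lyapunov(heterogeneous_model, x) > 0

    def test_rate_negative_off_the_z_profile(self, heterogeneous_model):
        x = mg.perturbed_initial_state(heterogeneous_model.x_star, 0.3, seed=9)
        assert mg.lyapunov_rate(heterogeneous_model, x) < 0

    def test_rate_zero_iff_profiles_proportional_to_z(self, heterogeneous_model):
        model = heterogeneous_model
        q = np.array([0.2, 0.5, 0.3])
        x = np.outer(q, model.z_star)  # every r_i proportional to z*
        assert mg.lyapunov_rate(model, x) == pytest.approx(0.0, abs=1e-15)

    def test_rejects_boundary_states(self, heterogeneous_model):
        x = heterogeneous_model.x_star.copy()
        x[0, 0] = 0.0
        with pytest.raises(ValueError):
            mg.lyapunov(heterogeneous_model, x)
        with pytest.raises(ValueError):
            mg.lyapunov_rate(heterogeneous_model, x)

    def test_rate_matches_finite_difference_along_trajectory(self, heterogeneous_model):
        model = heterogeneous_model
        x0 = mg.perturbed_initial_state(model.x_star, 0.3, seed=3)
        traj = mg.simulate(model, x0, t_end=5.0, n_samples=5001)
        fd = np.gradient(traj.lyapunov_values, traj.times)
        rates = np.array([mg.lyapunov_rate(model, s) for s in traj.states])
        assert np.abs(fd - rates)[2:-2].max() < 1e-6

    def test_monotone_non_increasing_heterogeneous(self, heterogeneous_model):
        x0 = mg.perturbed_initial_state(heterogeneous_model.x_star, 0.2, seed=2)
        traj = mg.simulate(heterogeneous_model, x0, t_end=100.0, n_samples=1001)
        assert np.diff(traj.lyapunov_values).max() < 1e-10


class TestClassifyLongrun:
    def test_started_at_equilibrium_converged(self, heterogeneous_model):
        traj = mg.simulate(heterogeneous_model, heterogeneous_model.x_star,
                           t_end=10.0, n_samples=101)
        assert mg.classify_longrun(heterogeneous_model, traj).label == "converged"

    def test_heterogeneous_converges(self, heterogeneous_model):
        x0 = mg.perturbed_initial_state(heterogeneous_model.x_star, 0.1)
        traj = mg.simulate(heterogeneous_model, x0, t_end=500.0, n_samples=1001)
        res = mg.classify_longrun(heterogeneous_model, traj)
        assert res.label == "converged"
        assert res.persistence_assumed

    def test_homogeneous_synchronized_limit_cycle(self, homogeneous_model):
        x0 = mg.load_example("example2").initial_state(homogeneous_model)
        traj = mg.simulate(homogeneous_model, x0, t_end=2000.0, n_samples=2001)
        res = mg.classify_longrun(homogeneous_model, traj)
        assert res.label == "limit_cycle_synchronized"
        assert res.cross_patch_spread < 1e-6
        assert res.lyapunov_final > 0
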