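"""Matrix-model construction, eigenvalues, equilibria and projections."""

import numpy as np
import pytest

import stagecast as sc
from stagecast.demography import A, R, S

from conftest import random_dispersal, random_rateset


class TestLocalMatrix:
    def test_hand_example(self):
        m = sc.build_local_matrix(theta=0.5, tau=0.2, phi=0.9, gamma=0.1, rho=2.0, retention=1.0)
        expected = np.array([[0, 0, 2.0], [0.1, 0.4, 0], [0, 0.1, 0.9]])
        np.testing.assert_allclose(m, expected)

    def test_all_zero_rates_give_zero_matrix(self):
        m = sc.build_local_matrix(0.0, 0.0, 0.0, 0.0, 0.0)
        assert not m.any()

    def test_zero_pattern_preserved(self):
        rng = np.random.default_rng(0)
        fixed_zero = np.array([[True, True, False],
                               [False, False, True],
                               [True, False, False]])
        for _ in range(25):
            m = sc.build_local_matrix(*rng.uniform(0.01, 0.99, 4), rho=rng.uniform(0.1, 5))
            assert np.all(m[fixed_zero] == 0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            sc.build_local_matrix(theta=1.2, phi=0.5, tau=0.1, gamma=0.1, rho=1.0)


class TestDispersalMatrix:
    def test_triangle_equal_split(self):
        topo = sc.DispersalTopology(
            plots=["a", "b", "c"],
            edges=[("a", "b"), ("b", "c"), ("a", "c")],
            retention=0.8,
        )
        D = sc.build_dispersal_matrix(topo)
        assert np.allclose(np.diag(D), 0.8)
        off = D[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.1)
        assert np.allclose(D.sum(axis=0), 1.0)

    def test_isolated_plot_column_is_unit_vector(self):
        topo = sc.DispersalTopology(plots=["a", "b", "c"], edges=[("a", "b")], retention=0.7)
        D = sc.build_dispersal_matrix(topo)
        np.testing.assert_allclose(D[:, 2], [0, 0, 1.0])

    def test_line_topology_column_sums(self):
        topo = sc.grid_topology(18, retention=0.9)
        assert len(topo.edges) == 17
        D = sc.build_dispersal_matrix(topo)
        assert np.allclose(D.sum(axis=0), 1.0, atol=1e-12)

    def test_loss_fraction_reduces_column_sums(self):
        topo = sc.DispersalTopology(plots=["a", "b"], edges=[("a", "b")], retention=0.8, loss=0.1)
        D = sc.build_dispersal_matrix(topo)
        assert np.allclose(D.sum(axis=0), 0.9)


class TestAssembleMetapop:
    def test_single_plot_full_retention_reduces_to_local(self):
        m = sc.build_local_matrix(0.5, 0.9, 0.2, 0.1, 2.0, retention=1.0)
        M = sc.assemble_metapop([m], np.eye(1), rho=2.0)
        np.testing.assert_allclose(M, m)

    def test_two_plot_line_hand_assembly(self):
        rho, ret = 2.0, 0.8
        D = np.array([[ret, 1 - ret], [1 - ret, ret]])
        locs = [sc.build_local_matrix(0.5, 0.9, 0.2, 0.1, rho, retention=ret)] * 2
        M = sc.assemble_metapop(locs, D, rho)
        # seedling row of plot 1 receives rho*D[0,1] from plot 2 adults
        assert M[0, 5] == pytest.approx(rho * D[0, 1])
        assert M[3, 2] == pytest.approx(rho * D[1, 0])
        assert M[0, 2] == pytest.approx(rho * ret)

    def test_matrix_multiplication_equals_expected_step(self):
        """Structural oracle: assembled metapopulation matrix action ==
        one mean-field step with frozen rates."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = int(rng.integers(1, 6))
            rates = random_rateset(rng, 1, p)
            D = random_dispersal(rng, p)
            locs = [
                sc.build_local_matrix(
                    rates.theta[0, j], rates.phi[0, j], rates.tau[0],
                    rates.gamma[0], rates.rho[0], retention=max(D[j, j], 1e-6),
                )
                for j in range(p)
            ]
            M = sc.assemble_metapop(locs, D, rates.rho[0])
            state = rng.uniform(0, 30, (1, p, 3))
            via_step = sc.expected_step(state, rates, D)
            via_matrix = (M @ state[0].ravel()).reshape(p, 3)
            np.testing.assert_allclose(via_matrix, via_step[0], atol=1e-10, rtol=0)

    def test_dimension_mismatch_rejected(self):
        m = sc.build_local_matrix(0.5, 0.9, 0.2, 0.1, 1.0)
        with pytest.raises(ValueError):
            sc.assemble_metapop([m, m], np.eye(3), 1.0)


class TestDominantEigenvalue:
    def test_cyclic_two_stage_closed_form(self):
        assert sc.dominant_eigenvalue(np.array([[0, 2.0], [0.5, 0]])) == pytest.approx(1.0, abs=1e-10)

    def test_identity(self):
        assert sc.dominant_eigenvalue(np.eye(3)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_solver_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            M = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.6)
            lam = sc.dominant_eigenvalue(M)
            dense = np.max(np.abs(np.linalg.eigvals(M)))
            assert lam == pytest.approx(dense, abs=1e-8)

    def test_local_matrix_matches_characteristic_polynomial_root(self):
        m = sc.build_local_matrix(0.5, 0.9, 0.2, 0.1, 2.0, retention=1.0)
        roots = np.roots(np.poly(m))
        assert sc.dominant_eigenvalue(m) == pytest.approx(
            np.max(np.abs(roots)), abs=1e-10
        )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            sc.dominant_eigenvalue(np.array([[0.1, -0.2], [0.3, 0.4]]))


def _regulated_single_species(base_theta=0.8, base_phi=0.93, intra_slope=-1.2):
    from scipy.special import logit

    return sc.SpeciesParams(
        name="solo",
        theta_coefs=[logit(base_theta), 0.0, intra_slope, 0.0],
        phi_coefs=[logit(base_phi), 0.0, intra_slope, 0.0],
        tau=0.25,
        gamma=0.3,
        rho=2.0,
    )


class TestEquilibrium:
    def test_declining_rates_reach_extinction(self):
        sp = sc.SpeciesParams(name="doom", theta_coefs=[-2.0, 0, 0, 0],
                              phi_coefs=[-1.0, 0, 0, 0], tau=0.1, gamma=0.05, rho=0.2)
        res = sc.find_equilibrium([sp], rain=0.0, D=np.eye(1),
                                  std=sc.Standardization(), tol=1e-12)
        assert res.converged
        np.testing.assert_allclose(res.state, 0.0, atol=1e-8)

    def test_interior_fixed_point_residual(self):
        sp = _regulated_single_species()
        std = sc.Standardization()
        res = sc.find_equilibrium([sp], rain=0.0, D=np.eye(1), std=std, tol=1e-12)
        assert res.converged
        assert res.state.sum() > 1.0  # interior, not extinct
        rates = sc.compute_rates([sp], float(std.rain(0.0)), res.state[:, :, A], std)
        nxt = sc.expected_step(res.state, rates, np.eye(1))
        np.testing.assert_allclose(nxt, res.state, atol=1e-9)

    def test_lambda_is_one_at_interior_equilibrium(self):
        """Perron-Frobenius: the local matrix evaluated at an interior
        fixed point has dominant eigenvalue exactly 1."""
        sp = _regulated_single_species()
        std = sc.Standardization()
        res = sc.find_equilibrium([sp], rain=0.0, D=np.eye(1), std=std, tol=1e-13)
        assert res.converged
        adults = res.state[0, 0, A]
        rates = sc.compute_rates([sp], float(std.rain(0.0)), res.state[:, :, A], std)
        m = sc.build_local_matrix(rates.theta[0, 0], rates.phi[0, 0],
                                  sp.tau, sp.gamma, sp.rho, retention=1.0)
        assert adults > 0
        assert sc.dominant_eigenvalue(m) == pytest.approx(1.0, abs=1e-6)


class TestProject:
    def test_zero_steps_returns_initial_state(self):
        sp = _regulated_single_species()
        init = np.array([[[5.0, 5.0, 10.0]]])
        traj = sc.project(init, [sp], np.empty(0), 0, np.eye(1), sc.Standardization())
        np.testing.assert_allclose(traj[0], init)
        assert traj.shape[0] == 1

    def test_frozen_rates_equal_matrix_powers(self):
        """With all slopes zero the mean-field projection is linear:
        repeated metapopulation-matrix multiplication."""
        from scipy.special import logit

        sp = sc.SpeciesParams(name="lin", theta_coefs=[logit(0.6), 0, 0, 0],
                              phi_coefs=[logit(0.8), 0, 0, 0], tau=0.2, gamma=0.3, rho=1.5)
        topo = sc.grid_topology(4, retention=0.85)
        D = sc.build_dispersal_matrix(topo)
        std = sc.Standardization()
        init = np.random.default_rng(0).uniform(1, 20, (1, 4, 3))
        n = 6
        traj = sc.project(init, [sp], np.full(n, std.rain_mean), n, D, std)
        rates = sc.compute_rates([sp], 0.0, init[:, :, A], std)
        locs = [
            sc.build_local_matrix(rates.theta[0, j], rates.phi[0, j], sp.tau,
                                  sp.gamma, sp.rho, retention=D[j, j])
            for j in range(4)
        ]
        M = sc.assemble_metapop(locs, D, sp.rho)
        vec = init[0].ravel()
        for _ in range(n):
            vec = M @ vec
        np.testing.assert_allclose(traj[-1][0].ravel(), vec, rtol=1e-9)

    def test_explosion_cap_raises(self):
        sp = sc.SpeciesParams(name="boom", theta_coefs=[3.0, 0, 0, 0],
                              phi_coefs=[3.0, 0, 0, 0], tau=0.5, gamma=0.9, rho=50.0)
        init = np.full((1, 1, 3), 100.0)
        with pytest.raises(RuntimeError, match="cap"):
            sc.project(init, [sp], np.full(60, 500.0), 60, np.eye(1),
                       sc.Standardization(), explosion_cap=1e5)
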