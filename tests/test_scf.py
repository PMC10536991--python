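import numpy as np
import pytest

from splinetb.gamma import gamma_kernel, gamma_matrix
from splinetb.geometry import Geometry
from splinetb.scf import (NotPositiveDefiniteError, SCFOptions,
                          dipole_moment, mulliken_populations, scf_solve,
                          solve_geometry)
from splinetb.slako import assemble_matrices, build_orbital_map, \
    n_valence_electrons


class TestGammaKernel:
    def test_long_range_coulomb_limit(self):
        g = gamma_kernel(50.0, 0.42, 0.37)
        assert abs(g - 1.0 / 50.0) < 1e-9

    def test_onsite_same_shell_equals_hubbard(self):
        for U in (0.3, 0.42, 0.52):
            assert abs(gamma_kernel(0.0, U, U) - U) < 1e-12

    def test_monotone_decreasing_and_bounded(self):
        Ua, Ub = 0.42, 0.36
        R = np.linspace(1e-4, 40.0, 4000)
        g = gamma_kernel(R, Ua, Ub)
        assert np.all(np.diff(g) < 0)
        assert np.all(g > 0)
        assert g[0] <= min(Ua, Ub) + 0.05
        # squeezed between 0 and the bare-Coulomb envelope
        assert np.all(g <= 1.0 / R + 1e-12)

    def test_matrix_invariants(self, toy_params_ho, water):
        gm = gamma_matrix(water, toy_params_ho)
        G = np.asarray(gm)
        assert np.allclose(G, G.T)
        omap = gm.orbital_map
        for s in range(omap.n_shells):
            z, l = int(omap.shell_element[s]), omap.shell_l[s]
            assert abs(G[s, s] - toy_params_ho.shell(z, l).hubbard) < 1e-12


class TestSCF:
    def test_non_scc_limit_single_diagonalization(self, toy_params_ho, water):
        mp = assemble_matrices(water, toy_params_ho)
        gm = gamma_matrix(water, toy_params_ho, mp.orbital_map)
        res = scf_solve(mp, gm, n_valence_electrons(water), geometry=water,
                        options=SCFOptions(gamma_scale=0.0))
        assert res.converged and res.n_iterations == 1
        assert abs(res.coulomb_energy) < 1e-15
        assert abs(res.electronic_energy
                   - np.sum(res.density_matrix * mp.H1)) < 1e-12

    def test_homonuclear_diatomic_zero_fluctuations(self, toy_params_ho, h2):
        res = solve_geometry(h2, toy_params_ho)
        assert res.converged
        assert np.max(np.abs(res.delta_q)) < 1e-10

    def test_electron_conservation(self, toy_params, small_dataset):
        for g in list(small_dataset)[:10]:
            res = solve_geometry(g, toy_params)
            pops = mulliken_populations(res.density_matrix, res.S,
                                        res.orbital_map)
            assert abs(pops.sum() - n_valence_electrons(g)) < 1e-10

    def test_fixed_point_and_energy_expression(self, toy_params, water):
        res = solve_geometry(water, toy_params)
        assert res.converged
        # re-entering the converged state changes dq by < 10x tolerance
        mp = assemble_matrices(water, toy_params)
        gm = gamma_matrix(water, toy_params, mp.orbital_map)
        G = np.asarray(gm)
        omap = mp.orbital_map
        shift = (G @ res.delta_q)[omap.shell_index]
        H = mp.H1 + 0.5 * mp.S * (shift[:, None] + shift[None, :])
        from scipy.linalg import eigh
        w, C = eigh(H, mp.S)
        nocc = n_valence_electrons(water) // 2
        P = 2 * C[:, :nocc] @ C[:, :nocc].T
        dq_new = mulliken_populations(P, mp.S, omap) - \
            mulliken_populations(res.density_matrix, res.S, omap) \
            + res.delta_q
        assert np.max(np.abs(dq_new - res.delta_q)) < 1e-6
        # independent energy expression
        e = (np.sum(P * mp.H1) + 0.5 * res.delta_q @ G @ res.delta_q
             + res.repulsive_energy + res.reference_energy)
        assert abs(e - res.total_energy) < 1e-10

    def test_variational_sanity(self, toy_params, small_dataset):
        # converged energy functional value <= first-iteration value
        for g in list(small_dataset)[:8]:
            full = solve_geometry(g, toy_params)
            one = solve_geometry(g, toy_params,
                                 options=SCFOptions(gamma_scale=1.0,
                                                    max_iter=1))
            e_one = (one.electronic_energy
                     + 0.5 * one.delta_q @ np.asarray(
                         gamma_matrix(g, toy_params)) @ one.delta_q)
            e_full = full.electronic_energy + full.coulomb_energy
            assert e_full <= e_one + 1e-12

    def test_nonconvergence_flagged_not_raised(self, toy_params, water):
        res = solve_geometry(water, toy_params,
                             options=SCFOptions(max_iter=2, tol=1e-14))
        assert not res.converged

    def test_odd_electron_count_rejected(self, toy_params_ho):
        g = Geometry(np.array([1]), np.zeros((1, 3)))
        mp = assemble_matrices(g, toy_params_ho)
        gm = gamma_matrix(g, toy_params_ho, mp.orbital_map)
        with pytest.raises(ValueError, match="even"):
            scf_solve(mp, gm, 1)

    def test_non_positive_definite_overlap_rejected(self, toy_params_ho,
                                                    water):
        mp = assemble_matrices(water, toy_params_ho)
        mp.S[:] = np.ones_like(mp.S)    # rank-1, not PD
        gm = gamma_matrix(water, toy_params_ho, mp.orbital_map)
        with pytest.raises(NotPositiveDefiniteError):
            scf_solve(mp, gm, 8)


class TestMullikenAndDipole:
    def test_identity_overlap_population_is_diagonal_sum(self, water):
        omap = build_orbital_map(water)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(omap.n_orb, omap.n_orb))
        P = A + A.T
        pops = mulliken_populations(P, np.eye(omap.n_orb), omap)
        d = np.diag(P)
        expect = np.zeros(omap.n_shells)
        np.add.at(expect, omap.shell_index, d)
        assert np.allclose(pops, expect)

    def test_h2_equilibrium_populations_exactly_one(self, toy_params_ho, h2):
        res = solve_geometry(h2, toy_params_ho)
        pops = mulliken_populations(res.density_matrix, res.S,
                                    res.orbital_map)
        assert np.allclose(pops, [1.0, 1.0], atol=1e-10)

    def test_zero_charges_zero_dipole(self, water):
        assert np.allclose(dipole_moment(water, np.zeros(3)), 0.0)

    def test_point_charge_dipole(self):
        g = Geometry(np.array([1, 1]),
                     np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]))
        d = dipole_moment(g, np.array([-0.1, 0.1]))
        assert np.allclose(d, [0.0, 0.0, 0.1])

    def test_neutral_molecule_dipole_origin_independent(self, toy_params,
                                                        water):
        res = solve_geometry(water, toy_params)
        shift = np.array([1.7, -2.3, 0.9])
        g2 = Geometry(water.atomic_numbers, water.coordinates + shift)
        d2 = dipole_moment(g2, res.charges)
        assert np.max(np.abs(d2 - res.dipole)) < 1e-12
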