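import numpy as np
import pytest
from scipy.optimize import minimize

from splinetb.qp import solve_qp
from splinetb.repulsive import (RankDeficientError, RepulsiveLayout,
                                fit_reference_energy,
                                fit_repulsive_and_reference,
                                repulsive_design_row, shape_constraints)
from splinetb.scf import solve_geometry
from splinetb.synth import make_targets, sample_geometries
from splinetb.units import HARTREE_TO_KCAL


class TestQP:
    def _slsqp(self, P, q, G, h):
        Gd = G.toarray() if hasattr(G, "toarray") else G
        res = minimize(lambda x: 0.5 * x @ P @ x + q @ x, np.zeros(len(q)),
                       jac=lambda x: P @ x + q,
                       constraints=[{"type": "ineq",
                                     "fun": lambda x: h - Gd @ x,
                                     "jac": lambda x: -Gd}],
                       method="SLSQP",
                       options={"maxiter": 800, "ftol": 1e-14})
        return res.fun

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_independent_solver(self, trial):
        rng = np.random.default_rng(trial)
        n, m = 10, 16
        A = rng.normal(size=(n, n))
        P = A @ A.T + np.eye(n)
        q = rng.normal(size=n)
        G = rng.normal(size=(m, n))
        h = rng.normal(size=m) + 1.0
        mine = solve_qp(P, q, G, h)
        ref = self._slsqp(P, q, G, h)
        assert abs(mine.objective - ref) <= 1e-8 * max(1.0, abs(ref))

    def test_restart_invariance(self):
        rng = np.random.default_rng(7)
        n, m = 12, 20
        A = rng.normal(size=(n, n))
        P = A @ A.T + 0.5 * np.eye(n)
        q = rng.normal(size=n)
        G = rng.normal(size=(m, n))
        h = rng.normal(size=m) + 2.0
        objs = []
        for k in range(5):
            x0 = rng.normal(size=n) * 0.3
            # project to a feasible point by backtracking toward zero
            while np.any(G @ x0 > h):
                x0 *= 0.5
            objs.append(solve_qp(P, q, G, h, x0=x0).objective)
        objs = np.array(objs)
        assert np.max(np.abs(objs - objs[0])) <= 1e-8 * max(1.0,
                                                            abs(objs[0]))


class TestReferenceFit:
    def test_identical_energies_zero_coefficients(self):
        counts = [{1: 2}, {1: 2, 8: 1}, {6: 1, 1: 4}, {6: 1, 8: 1, 1: 2},
                  {1: 4, 8: 2}]
        e = np.array([-1.0, -17.2, -8.3, -22.4, -35.0])
        ref, resid = fit_reference_energy(e, e, counts)
        assert all(abs(c) < 1e-12 for c in ref.c_per_element.values())
        assert abs(ref.c0) < 1e-12
        assert np.max(np.abs(resid)) < 1e-12

    def test_injected_offsets_recovered_exactly(self):
        rng = np.random.default_rng(0)
        counts = [{1: rng.integers(1, 9), 6: rng.integers(0, 4),
                   8: rng.integers(0, 3)} for _ in range(40)]
        ea = rng.normal(-10, 3, 40)
        true = {1: 0.017, 6: -0.23, 8: 0.41}
        c0 = -0.055
        eb = ea + np.array([sum(n * true[z] for z, n in c.items()) + c0
                            for c in counts])
        ref, resid = fit_reference_energy(ea, eb, counts)
        for z, c in true.items():
            assert abs(ref.c_per_element[z] - c) < 1e-12
        assert abs(ref.c0 - c0) < 1e-12
        assert np.max(np.abs(resid)) < 1e-12

    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        counts = [{1: rng.integers(1, 9), 6: rng.integers(0, 4),
                   8: rng.integers(0, 3)} for _ in range(30)]
        ea = rng.normal(-10, 3, 30)
        eb = ea + rng.normal(0, 0.1, 30)
        ref, resid = fit_reference_energy(ea, eb, counts)
        for z in (1, 6, 8):
            col = np.array([c.get(z, 0) for c in counts])
            assert abs(resid @ col) < 1e-10
        assert abs(resid.sum()) < 1e-10

    def test_rank_deficient_names_columns(self):
        counts = [{1: 2}] * 5
        e = np.zeros(5)
        with pytest.raises(RankDeficientError, match="N_1"):
            fit_reference_energy(e, e, counts)


def _pair_dists(g):
    from splinetb.params import canonical_pair
    dm = g.distance_matrix()
    out = []
    for i in range(g.n_atoms):
        for j in range(i + 1, g.n_atoms):
            out.append((canonical_pair(int(g.atomic_numbers[i]),
                                       int(g.atomic_numbers[j])),
                        dm[i, j]))
    return out


@pytest.fixture(scope="module")
def rep_setup(toy_params):
    geoms = sample_geometries(
        templates=("H2", "H2O", "CH4", "H2CO", "CH3OH", "NH3"),
        n_per_template=12, seed=9)
    ds = make_targets(geoms, toy_params,
                      element_offsets={1: 0.05, 6: -0.08, 7: 0.03, 8: 0.11},
                      seed=10)
    elec = []
    for g in ds:
        res = solve_geometry(g, toy_params, include_repulsive=False)
        elec.append(res.electronic_energy + res.coulomb_energy)
    targ = [g.targets["toy-truth"]["energy"] for g in ds]
    return ds, np.array(elec), np.array(targ)


class TestRepulsiveFit:
    def test_zero_when_targets_equal_electronic(self, toy_params, rep_setup):
        ds, elec, _ = rep_setup
        params = toy_params.copy()
        _, res, resid = fit_repulsive_and_reference(ds, elec, elec, params)
        assert res.objective < 1e-8
        assert np.max(np.abs(resid)) < 1e-5
        # the fitted walls vanish wherever the data constrains them (below
        # the sampled range only the shape constraints act)
        from splinetb.experiments import sampled_pair_ranges
        ranges = sampled_pair_ranges(ds, 5, 95)
        for pair, (lo, hi) in ranges.items():
            sp = params.repulsive[pair]
            hi_eff = min(hi, sp.r_cut)
            if hi_eff <= lo:
                continue
            r = np.linspace(lo, hi_eff, 30)
            assert np.max(np.abs(sp.eval(r))) < 1e-4

    def test_recovers_generating_repulsive_and_offsets(self, toy_params,
                                                       rep_setup):
        ds, elec, targ = rep_setup
        params = toy_params.copy()
        for sp in params.repulsive.values():
            sp.free = np.zeros_like(sp.free)
        params_before = {p: toy_params.repulsive[p].copy()
                         for p in toy_params.repulsive}
        layout, res, resid = fit_repulsive_and_reference(ds, elec, targ,
                                                         params)
        # the fit reproduces the generating targets essentially exactly
        assert np.max(np.abs(resid)) * HARTREE_TO_KCAL < 0.05
        # gauge-invariant check: total repulsive + reference energy per
        # configuration equals the truth's repulsive + injected offsets
        # (per-bond constants within the sampled band are collinear with
        # composition, so the split between R levels and element offsets is
        # a gauge; only their sum enters any observable energy)
        offsets = {1: 0.05, 6: -0.08, 7: 0.03, 8: 0.11}
        from splinetb.scf import repulsive_energy
        for g in list(ds)[:20]:
            fit_e = (repulsive_energy(g, params)
                     + params.reference(g.element_counts()))
            true_e = (sum(n * offsets[z]
                          for z, n in g.element_counts().items())
                      + sum(params_before[p].eval(np.array([d]))[0]
                            for p, d in _pair_dists(g)))
            assert abs(fit_e - true_e) * HARTREE_TO_KCAL < 0.1
        # recovered repulsive shape (up to its per-pair gauge constant)
        # within 0.1 kcal/mol over distances actually sampled inside the
        # repulsive range (pair-distance distributions are multimodal:
        # between the bonded and nonbonded bands nothing constrains the fit)
        acc = {}
        for g in ds:
            for p, dist in _pair_dists(g):
                acc.setdefault(p, []).append(dist)
        for pair, dists in acc.items():
            truth_sp = params_before[pair]
            sp = params.repulsive[pair]
            d_in = np.array([x for x in dists
                             if x < min(sp.r_cut, truth_sp.r_cut)])
            if len(d_in) < 10:
                continue
            lo, hi = np.percentile(d_in, [5, 95])
            r = np.linspace(lo, hi, 40)
            dv = sp.eval(r) - truth_sp.eval(r)
            err = np.max(np.abs(dv - dv.mean()))
            assert err * HARTREE_TO_KCAL < 0.1, (pair, err * HARTREE_TO_KCAL)

    def test_boundary_conditions_exact(self, toy_params, rep_setup):
        ds, elec, targ = rep_setup
        params = toy_params.copy()
        fit_repulsive_and_reference(ds, elec, targ, params)
        for sp in params.repulsive.values():
            rc = np.array([sp.r_cut - 1e-12])
            assert abs(sp.eval(rc)[0]) < 1e-12
            assert abs(sp.eval(rc, 1)[0]) < 1e-10

    def test_shape_constraints_satisfied(self, toy_params, rep_setup):
        ds, elec, targ = rep_setup
        params = toy_params.copy()
        fit_repulsive_and_reference(ds, elec, targ, params)
        for sp in params.repulsive.values():
            r = sp.grid(200)
            r = r[r < sp.r_cut]
            assert np.all(sp.eval(r, 1) <= 1e-7)      # monotone decreasing
            assert np.all(sp.eval(r, 2) >= -1e-6)     # convex


def test_repulsive_program_matches_slsqp_small_instance(toy_params):
    # 50-configuration single-pair instance small enough for the generic
    # solver to handle
    geoms = sample_geometries(templates=("H2",), n_per_template=50, seed=1)
    ds = make_targets(geoms, toy_params, seed=2)
    elec, targ = [], []
    for g in ds:
        res = solve_geometry(g, toy_params, include_repulsive=False)
        elec.append(res.electronic_energy + res.coulomb_energy)
        targ.append(g.targets["toy-truth"]["energy"])
    params = toy_params.copy()
    from splinetb.bspline import make_repulsive_spline
    params.repulsive = {(1, 1): make_repulsive_spline((1, 1), 0.55, 1.2, 12)}
    params.hamiltonian = {(1, 1): params.hamiltonian[(1, 1)]}
    params.overlap = {(1, 1): params.overlap[(1, 1)]}
    params.shells = {1: params.shells[1]}
    layout = RepulsiveLayout.from_params(params)
    D = np.vstack([repulsive_design_row(g, params, layout) for g in ds])
    y = np.array(targ) - np.array(elec)
    P = 2.0 * D.T @ D + 1e-10 * np.eye(layout.n_total)
    q = -2.0 * D.T @ y
    G, h = shape_constraints(params, layout, grid_n=60)
    mine = solve_qp(P, q, G, h)
    Gd = G.toarray()
    ref = minimize(lambda x: 0.5 * x @ P @ x + q @ x,
                   np.zeros(layout.n_total), jac=lambda x: P @ x + q,
                   constraints=[{"type": "ineq",
                                 "fun": lambda x: h - Gd @ x,
                                 "jac": lambda x: -Gd}],
                   method="SLSQP", options={"maxiter": 2000, "ftol": 1e-16})
    scale = max(abs(ref.fun), abs(y @ y))
    assert abs(mine.objective - ref.fun) <= 1e-8 * scale
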