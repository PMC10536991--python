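import numpy as np
import pytest

from splinetb.data import DatasetSplit
from splinetb.loss import LossConfig, MissingTargetError, compute_loss
from splinetb.regularization import PenaltyConfig
from splinetb.synth import (make_targets, sample_geometries, seed_paramset,
                            sign_classes_of)
from splinetb.train import TrainConfig, make_batches, train


class TestComputeLoss:
    def _preds(self, n=3):
        return {"energy": np.array([-1.0, -2.0, -3.0][:n]),
                "dipole": np.zeros((n, 3)),
                "charges": [np.zeros(2)] * n,
                "n_heavy": np.ones(n)}

    def test_perfect_predictions_zero_loss(self):
        p = self._preds()
        t = {"energy": p["energy"].copy(), "dipole": p["dipole"].copy(),
             "charges": [c.copy() for c in p["charges"]]}
        total, comps = compute_loss(p, t, LossConfig())
        assert total == 0.0
        assert all(v == 0.0 for v in comps.values())

    def test_weight_quadratic_homogeneity(self):
        p = self._preds()
        t = {"energy": p["energy"] + 0.01, "dipole": p["dipole"] + 0.1,
             "charges": [c + 0.05 for c in p["charges"]]}
        _, c1 = compute_loss(p, t, LossConfig(w_energy=100.0, w_dipole=10.0,
                                              w_charge=1.0))
        _, c2 = compute_loss(p, t, LossConfig(w_energy=200.0, w_dipole=10.0,
                                              w_charge=1.0))
        assert abs(c2["energy"] - 4.0 * c1["energy"]) < 1e-9 * c1["energy"]
        assert c2["dipole"] == c1["dipole"]

    def test_hand_evaluated_single_molecule(self):
        # one molecule with 2 heavy atoms: energy residual 0.002 Ha, one
        # dipole component off by 0.03 e*angstrom, one charge off by 0.1 e
        p = {"energy": np.array([-5.0]), "dipole": np.array([[0.03, 0, 0]]),
             "charges": [np.array([0.1, 0.0])], "n_heavy": np.array([2.0])}
        t = {"energy": np.array([-5.002]), "dipole": np.zeros((1, 3)),
             "charges": [np.zeros(2)]}
        total, comps = compute_loss(p, t, LossConfig())
        assert abs(comps["energy"] - (6270.0 * 0.002 / 2.0) ** 2) < 1e-9
        assert abs(comps["dipole"] - (100.0 * 0.03) ** 2 / 3.0) < 1e-12
        assert abs(comps["charge"] - (1.0 * 0.1) ** 2 / 2.0) < 1e-15
        assert abs(total - sum(comps.values())) < 1e-9

    def test_missing_target_raises(self):
        p = self._preds()
        t = {"energy": p["energy"], "dipole": None, "charges": p["charges"]}
        with pytest.raises(MissingTargetError, match="dipole"):
            compute_loss(p, t, LossConfig())


class TestMakeBatches:
    def test_sizes(self, small_dataset):
        batches, _ = make_batches(small_dataset[:35], 10, seed=0)
        assert sorted(len(b) for b in batches) == [5, 10, 10, 10]

    def test_same_seed_identical_membership(self, small_dataset):
        b1, _ = make_batches(small_dataset, 10, seed=3)
        b2, _ = make_batches(small_dataset, 10, seed=3)
        assert b1 == b2

    def test_union_is_dataset_no_duplicates(self, small_dataset):
        for seed in range(20):
            batches, _ = make_batches(small_dataset, 7, seed=seed)
            flat = [i for b in batches for i in b]
            assert sorted(flat) == list(range(len(small_dataset)))

    def test_shuffler_permutes_order_only(self, small_dataset):
        batches, shuffler = make_batches(small_dataset, 10, seed=1)
        o1, o2 = shuffler(), shuffler()
        assert sorted(o1) == list(range(len(batches)))
        assert not np.array_equal(o1, o2)    # reshuffles across epochs


@pytest.fixture(scope="module")
def tiny_split(toy_params):
    geoms = sample_geometries(templates=("H2", "H2O", "CH4", "H2CO"),
                              n_per_template=12, seed=20)
    ds = make_targets(geoms, toy_params, element_offsets={1: 0.01, 6: -0.02,
                                                          8: 0.03}, seed=21)
    train_idx = [i for i, g in enumerate(ds)
                 if g.empirical_formula in ("H2", "H2O", "CH4")]
    val_idx = [i for i, g in enumerate(ds)
               if g.empirical_formula == "CH2O"]
    return DatasetSplit(train=ds.subset(train_idx),
                        validation=ds.subset(val_idx),
                        test=ds.subset([]))


def _seed_for(split):
    from splinetb.synth import ranges_from_data
    from splinetb.geometry import Dataset
    all_ds = Dataset(list(split.train) + list(split.validation))
    ranges = ranges_from_data(all_ds, sorted(all_ds.elements()))
    return seed_paramset(sorted(all_ds.elements()), pair_ranges=ranges,
                         n_knots_elec=40, n_knots_rep=20)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_split):
        init = _seed_for(tiny_split)
        from splinetb.engine import ParamLayout
        layout = ParamLayout(init)
        before = layout.pack(init)
        res = train(tiny_split, init,
                    TrainConfig(epochs=4, charge_update_period=2,
                                learning_rate=0.0, seed=0),
                    LossConfig(), PenaltyConfig(),
                    sign_classes=sign_classes_of(init))
        after = ParamLayout(res.params).pack(res.params)
        assert np.array_equal(before, after)

    def test_bitwise_reproducible_history(self, tiny_split):
        init = _seed_for(tiny_split)
        kw = dict(train_config=TrainConfig(epochs=6, charge_update_period=3,
                                           seed=5),
                  loss_config=LossConfig(),
                  penalty_config=PenaltyConfig(),
                  sign_classes=sign_classes_of(init))
        r1 = train(tiny_split, init, **kw)
        r2 = train(tiny_split, init, **kw)
        assert r1.history["train_loss"] == r2.history["train_loss"]
        assert r1.history["val_loss"] == r2.history["val_loss"]

    def test_loop_inversion_consistency_at_refresh(self, tiny_split,
                                                   toy_params):
        # right after a refresh, the frozen-charge loss equals a loss built
        # from per-geometry self-consistent solutions
        from splinetb.engine import (ParamLayout, forward, precompute_batch,
                                     scc_refresh)
        from splinetb.loss import batch_loss_and_adjoints
        from splinetb.repulsive import RepulsiveLayout
        from splinetb.scf import solve_geometry
        init = _seed_for(tiny_split)
        layout = ParamLayout(init)
        rl = RepulsiveLayout.from_params(init)
        cache = precompute_batch(list(tiny_split.train), init, layout, rl)
        theta = layout.pack(init)
        rep_vec = rl.pack(init)
        conv, _ = scc_refresh(cache, theta, layout)
        assert conv.all()
        fw = forward(cache, theta, layout, rep_vec, need_grad=False)
        frozen_loss, *_ = batch_loss_and_adjoints(fw, cache, LossConfig())
        e, d, c = [], [], []
        for g in tiny_split.train:
            res = solve_geometry(g, init)
            e.append(res.total_energy)
            d.append(res.dipole)
            c.append(res.charges)
        preds = {"energy": np.array(e), "dipole": np.array(d), "charges": c,
                 "n_heavy": np.array([g.n_heavy for g in tiny_split.train])}
        targs = {"energy": np.array([g.targets["toy-truth"]["energy"]
                                     for g in tiny_split.train]),
                 "dipole": np.array([g.targets["toy-truth"]["dipole"]
                                     for g in tiny_split.train]),
                 "charges": [g.targets["toy-truth"]["charges"]
                             for g in tiny_split.train]}
        scf_loss, _ = compute_loss(preds, targs, LossConfig())
        assert abs(frozen_loss - scf_loss) < 1e-8 * max(1.0, scf_loss)

    def test_large_convex_weight_enforces_shape_after_training(self,
                                                               tiny_split):
        # paired runs with and without penalties: the penalized run must end
        # with no curvature-sign violation at any grid point, and its
        # residual penalty cannot exceed the unpenalized run's
        from splinetb.engine import ParamLayout
        from splinetb.regularization import PenaltyEngine
        init = _seed_for(tiny_split)
        signs = sign_classes_of(init)
        cfg = TrainConfig(epochs=10, charge_update_period=5, seed=2,
                          learning_rate=1e-4)
        pen_on = PenaltyConfig(convex_weight=1e6, smoothing_weight=1e-5)
        r_off = train(tiny_split, init, cfg, LossConfig(),
                      PenaltyConfig(convex_weight=0.0, smoothing_weight=0.0),
                      sign_classes=signs)
        r_on = train(tiny_split, init, cfg, LossConfig(), pen_on,
                     sign_classes=signs)
        probe = PenaltyConfig(convex_weight=1.0, smoothing_weight=0.0)
        lay_on = ParamLayout(r_on.params)
        v_on, _ = PenaltyEngine(r_on.params, lay_on, probe,
                                signs).value_and_grad(
                                    lay_on.pack(r_on.params))
        lay_off = ParamLayout(r_off.params)
        v_off, _ = PenaltyEngine(r_off.params, lay_off, probe,
                                 signs).value_and_grad(
                                     lay_off.pack(r_off.params))
        # the quadratic hinge leaves a transient violation that decays over
        # training; after these few epochs it is already small on the
        # f'' ~ O(1) scale and far below the unpenalized run's
        assert v_on < 1e-3
        assert v_on < 1e-2 * v_off

    def test_validation_mae_decreases_across_refresh_cycles(self, tiny_split):
        init = _seed_for(tiny_split)
        res = train(tiny_split, init,
                    TrainConfig(epochs=30, charge_update_period=10, seed=3,
                                learning_rate=1e-4),
                    LossConfig(), PenaltyConfig(),
                    sign_classes=sign_classes_of(init))
        v = res.history["val_data_loss"]
        assert v[-1] < v[0]


def test_invalid_config_validation():
    with pytest.raises(ValueError, match="divide"):
        TrainConfig(epochs=25, charge_update_period=10)
    with pytest.raises(ValueError, match="batch_size"):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError, match="nonnegative"):
        LossConfig(w_energy=-1.0)
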