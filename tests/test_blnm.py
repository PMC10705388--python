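"""Surrogate architecture, training and prediction tests."""

import numpy as np
import pytest

from cardiotwin import blnm
from cardiotwin.blnm import BLNMConfig, EcgDataset, count_parameters, forward, init_weights
from cardiotwin.ecg import Normalizer


def toy_dataset(n_samples=4, T=21, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 600.0, T)
    params_norm = rng.uniform(-1, 1, (n_samples, 7))
    # smooth synthetic "leads": parameter-modulated bumps
    leads = np.empty((n_samples, 9, T))
    tt = t / 600.0
    for i in range(n_samples):
        for l in range(9):
            c = 0.3 + 0.4 * (params_norm[i, l % 7] + 1) / 2
            leads[i, l] = np.exp(-((tt - c) ** 2) / 0.02) * np.sin(3 * tt + l)
    norm = Normalizer(lo=-np.ones(9), hi=np.ones(9))
    return EcgDataset(
        t=t, params=params_norm.copy(), params_norm=params_norm, leads=leads,
        train_idx=np.arange(n_samples), test_idx=np.array([], dtype=int),
        normalizer=norm,
    )


class TestArchitecture:
    @pytest.mark.parametrize(
        "cfg,expected",
        [
            (BLNMConfig(7, 19, 10, 2), 2398),   # published optimized configuration
            (BLNMConfig(7, 19, 10, 7), 1498),
            (BLNMConfig(1, 10, 9, 1), 149),
        ],
    )
    def test_closed_form_counts(self, cfg, expected):
        assert count_parameters(cfg) == expected

    def test_count_matches_instantiated_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(1, 9))
            cfg = BLNMConfig(L, int(rng.integers(10, 31)), int(rng.integers(9, 13)),
                             int(rng.integers(1, L + 1)))
            assert count_parameters(cfg) == len(init_weights(cfg, 1))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BLNMConfig(3, 10, 8, 1)       # fewer outputs than physical leads
        with pytest.raises(ValueError):
            BLNMConfig(3, 10, 10, 4)      # d > layers

    def test_weight_length_mismatch_rejected(self):
        cfg = BLNMConfig(2, 10, 9, 1)
        with pytest.raises(ValueError):
            forward(cfg, np.zeros(10), np.array([0.5]), np.zeros(7))


class TestForward:
    def test_zero_weights_zero_output(self):
        cfg = BLNMConfig(3, 12, 10, 2)
        out = forward(cfg, np.zeros(count_parameters(cfg)),
                      np.linspace(0, 1, 5), np.random.default_rng(0).uniform(-1, 1, (5, 7)))
        assert np.all(out == 0.0)

    def test_deterministic(self):
        cfg = BLNMConfig(3, 12, 10, 2)
        w = init_weights(cfg, 4)
        t = np.linspace(0, 1, 7)
        th = np.random.default_rng(1).uniform(-1, 1, (7, 7))
        assert np.array_equal(forward(cfg, w, t, th), forward(cfg, w, t, th))

    def test_disentanglement_blocks_parameter_leakage(self):
        """Before the merge layer, temporal-branch activations must not
        depend on the parameters (partial connectivity contract)."""
        cfg = BLNMConfig(4, 12, 10, 4)  # fully branched
        w = init_weights(cfg, 2)
        t = np.linspace(0, 1, 9)
        rng = np.random.default_rng(3)
        out1, jac1 = blnm.forward_with_param_jac(cfg, w, t, rng.uniform(-1, 1, 7))
        # with d = n_layers the output's parameter dependence flows only
        # through the parameter branch: zeroing those output weights
        # kills the whole Jacobian
        blocks = blnm._unflatten(cfg, w.copy())
        w2 = w.copy()
        # zero the output-weight rows fed by the parameter branch
        k = 0
        for n_in, n_out, kind in blnm._layer_dims(cfg):
            if kind == "out":
                W = w2[k : k + n_in * n_out].reshape(n_in, n_out)
                W[cfg.width_t :, :] = 0.0
            k += n_in * n_out + n_out
        _, jac2 = blnm.forward_with_param_jac(cfg, w2, t, rng.uniform(-1, 1, 7))
        assert np.abs(jac2).max() < 1e-14

    def test_gradient_matches_finite_differences(self):
        cfg = BLNMConfig(3, 11, 10, 2)
        rng = np.random.default_rng(5)
        w = init_weights(cfg, 5)
        t = np.linspace(0, 1, 8)
        th = rng.uniform(-1, 1, (8, 7))
        y = rng.uniform(-1, 1, (8, 9))
        l0, g = blnm.loss_and_grad(cfg, w, t, th, y)
        idx = rng.integers(0, len(w), 12)
        eps = 1e-6
        for i in idx:
            wp = w.copy()
            wp[i] += eps
            num = (blnm.loss_and_grad(cfg, wp, t, th, y)[0] - l0) / eps
            assert num == pytest.approx(g[i], abs=1e-6)

    def test_param_jacobian_matches_finite_differences(self):
        cfg = BLNMConfig(3, 11, 10, 1)
        w = init_weights(cfg, 7)
        t = np.linspace(0, 1, 6)
        th = np.random.default_rng(8).uniform(-0.5, 0.5, (6, 7))
        out, jac = blnm.forward_with_param_jac(cfg, w, t, th)
        eps = 1e-6
        th2 = th.copy()
        th2[:, 2] += eps
        num = (forward(cfg, w, t, th2) - out) / eps
        assert np.abs(num - jac[:, :, 2]).max() < 1e-5


class TestTraining:
    def test_single_sample_interpolation(self):
        ds = toy_dataset(n_samples=1)
        cfg = BLNMConfig(2, 12, 9, 1)
        model = blnm.train(cfg, ds, max_iters=2000, seed=0)
        tt, th, y = ds.rows(np.array([0]))
        assert blnm.dataset_mse(None, cfg, model.weights, tt, th, y) < 1e-5

    def test_seeded_determinism(self):
        ds = toy_dataset(n_samples=3)
        cfg = BLNMConfig(2, 10, 9, 1)
        m1 = blnm.train(cfg, ds, max_iters=150, seed=9)
        m2 = blnm.train(cfg, ds, max_iters=150, seed=9)
        assert np.array_equal(m1.weights, m2.weights)

    def test_initial_loss_equals_independent_mse(self):
        ds = toy_dataset(n_samples=3)
        cfg = BLNMConfig(2, 10, 9, 1)
        w0 = init_weights(cfg, 3)
        tt, th, y = ds.rows(ds.train_idx)
        loss, _ = blnm.loss_and_grad(cfg, w0, tt, th, y)
        out = forward(cfg, w0, tt, th)
        assert loss == pytest.approx(np.mean((out[:, :9] - y) ** 2), rel=1e-12)

    def test_loss_history_decreases(self):
        ds = toy_dataset(n_samples=2)
        model = blnm.train(BLNMConfig(2, 10, 9, 1), ds, max_iters=300, seed=1)
        h = np.array(model.loss_history)
        assert h[-1] < h[0]


class TestKFoldTune:
    def test_argmin_and_fold_contracts(self):
        ds = toy_dataset(n_samples=10)
        best, table = blnm.kfold_tune(ds, K=5, n_configs=4, iters_per_fit=30, seed=0)
        assert table["cv_mse"].min() == table.set_index(
            ["n_layers", "n_neurons", "n_states", "disentanglement"]
        ).loc[(best.n_layers, best.n_neurons, best.n_states, best.disentanglement), "cv_mse"]
        assert np.all(table["disentanglement"] <= table["n_layers"])
        assert np.all((table["n_states"] >= 9) & (table["n_states"] <= 12))

    def test_folds_partition_training_set(self):
        rng = np.random.default_rng(0)
        idx = rng.permutation(23)
        folds = np.array_split(idx, 5)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == sorted(idx)


class TestPredict12Lead:
    def test_shapes_and_lead_identity(self):
        ds = toy_dataset()
        cfg = BLNMConfig(2, 10, 10, 1)
        w = init_weights(cfg, 0)
        e = blnm.predict_12lead(cfg, w, np.zeros(7), ds.t, ds.normalizer)
        assert e.traces.shape == (12, len(ds.t))
        assert np.abs(e.lead("I") + e.lead("III") - e.lead("II")).max() < 1e-12

    def test_matches_training_sample_after_overfit(self):
        ds = toy_dataset(n_samples=1)
        cfg = BLNMConfig(2, 12, 9, 1)
        model = blnm.train(cfg, ds, max_iters=2000, seed=0)
        e = blnm.predict_12lead(cfg, model.weights, ds.params_norm[0], ds.t, ds.normalizer)
        stored = ds.leads[0]
        assert np.abs(e.traces[:6] - stored[:6]).max() < 0.05
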