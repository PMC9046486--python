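import numpy as np
import pytest

from tbarskinetics import (
    DataError,
    MLPEnsembleRegressor,
    TBARSSeries,
    encode_inputs,
    predict_ensemble,
    select_ensemble,
    split_dataset,
)
from tbarskinetics.ann import (
    FeatureScaling,
    TrainedNetwork,
    _forward,
    _loss_grad,
    _n_params,
)


class TestEncodeInputs:
    def test_control_row_encoding(self, study_seed7):
        X, y = encode_inputs(study_seed7)
        assert X.shape[1] == 16
        controls = [s for s in study_seed7 if s.sample_label == "Control"]
        Xc, yc = encode_inputs(controls[:1])
        labels_onehot = Xc[0, :14]
        assert labels_onehot.sum() == 1.0
        assert Xc[0, 14] == 0.0  # day 0 row first
        assert yc[0] == 100.0

    def test_identical_rows_encode_identically(self, study_seed7):
        X1, y1 = encode_inputs(study_seed7[:3])
        X2, y2 = encode_inputs(study_seed7[:3])
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_unknown_label_rejected(self):
        s = TBARSSeries("Vanilla", 277.15, 1, (0, 1, 2), percent_values=(100, 110, 121))
        with pytest.raises(DataError):
            encode_inputs([s])


class TestSplitDataset:
    def test_ratio_arithmetic(self):
        tr, val, te = split_dataset(400, (2, 1, 1), seed=0)
        assert (len(tr), len(val), len(te)) == (200, 100, 100)

    def test_reproducible_and_exhaustive(self):
        a = split_dataset(101, (2, 1, 1), seed=5)
        b = split_dataset(101, (2, 1, 1), seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        merged = np.sort(np.concatenate(a))
        np.testing.assert_array_equal(merged, np.arange(101))
        sizes = [len(x) for x in a]
        for size, frac in zip(sizes, (0.5, 0.25, 0.25)):
            assert abs(size - 101 * frac) <= 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError):
            split_dataset(5, (2, 1, 1), seed=0)


class TestNetworkInternals:
    def test_16_8_1_has_145_weights(self):
        assert _n_params(16, 8) == 145

    @pytest.mark.parametrize("hidden", ["tanh", "logistic"])
    @pytest.mark.parametrize("output", ["exponential", "logistic"])
    def test_analytic_gradient_matches_finite_differences(self, hidden, output):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (12, 4))
        y = rng.uniform(0.2, 0.8, 12)
        w = rng.normal(0, 0.5, _n_params(4, 3))
        loss, grad = _loss_grad(w, X, y, 4, 3, hidden, output)
        num = np.empty_like(w)
        eps = 1e-6
        for i in range(w.size):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            num[i] = (
                _loss_grad(wp, X, y, 4, 3, hidden, output)[0]
                - _loss_grad(wm, X, y, 4, 3, hidden, output)[0]
            ) / (2 * eps)
        np.testing.assert_allclose(grad, num, atol=1e-6)


def _fake_net(seed, val_r2, val_error=1.0, failed=False):
    return TrainedNetwork(
        hidden_size=3, hidden_activation="tanh", output_activation="logistic",
        seed=seed, weights=np.zeros(_n_params(2, 3)), val_r2=val_r2,
        val_error=val_error, failed=failed,
    )


def _unit_scaling(n_features=2):
    return FeatureScaling(
        x_min=np.zeros(n_features), x_max=np.ones(n_features), y_min=0.0, y_max=1.0
    )


class TestSelectEnsemble:
    def test_top_five_by_validation_r2(self):
        nets = [_fake_net(i, val_r2=i / 20) for i in range(20)]
        ens = select_ensemble(nets, _unit_scaling())
        assert [m.seed for m in ens.members] == [19, 18, 17, 16, 15]

    def test_tie_break_by_error_then_seed(self):
        nets = [
            _fake_net(3, 0.9, val_error=0.5),
            _fake_net(1, 0.9, val_error=0.5),
            _fake_net(2, 0.9, val_error=0.4),
            _fake_net(4, 0.8),
            _fake_net(5, 0.7),
            _fake_net(6, 0.6),
        ]
        ens = select_ensemble(nets, _unit_scaling())
        assert [m.seed for m in ens.members] == [2, 1, 3, 4, 5]

    def test_too_few_successes_rejected(self):
        nets = [_fake_net(i, 0.5, failed=i < 16) for i in range(20)]
        with pytest.raises(DataError, match="4 successful"):
            select_ensemble(nets, _unit_scaling())


class TestPredictEnsemble:
    def test_identical_members_equal_single_member(self):
        rng = np.random.default_rng(1)
        w = rng.normal(0, 0.5, _n_params(2, 3))
        nets = [
            TrainedNetwork(3, "tanh", "logistic", seed=i, weights=w.copy())
            for i in range(5)
        ]
        scaling = _unit_scaling()
        ens = select_ensemble(nets, scaling)
        X = rng.uniform(0, 1, (7, 2))
        single, _ = _forward(w, X, 2, 3, "tanh", "logistic")
        np.testing.assert_allclose(
            predict_ensemble(ens, X), scaling.unscale_y(single), atol=1e-12
        )

    def test_empty_rows_give_empty_predictions(self):
        nets = [_fake_net(i, 0.5) for i in range(5)]
        ens = select_ensemble(nets, _unit_scaling())
        assert predict_ensemble(ens, np.empty((0, 2))).size == 0

    def test_scaling_mismatch_rejected(self):
        nets = [_fake_net(i, 0.5) for i in range(5)]
        ens = select_ensemble(nets, _unit_scaling())
        with pytest.raises(DataError):
            predict_ensemble(ens, np.zeros((3, 7)))


@pytest.fixture(scope="module")
def fitted(study_seed7):
    X, y = encode_inputs(study_seed7)
    reg = MLPEnsembleRegressor(random_state=11).fit(X, y)
    return X, y, reg


class TestMLPEnsembleRegressor:
    def test_search_protocol_counts(self, fitted):
        X, y, reg = fitted
        assert len(reg.candidates_) == 20
        assert len(reg.ensemble_.members) == 5
        val_r2s = [m.val_r2 for m in reg.ensemble_.members]
        assert val_r2s == sorted(val_r2s, reverse=True)

    def test_best_network_validation_r2(self, fitted):
        _, _, reg = fitted
        assert reg.ensemble_.members[0].val_r2 >= 0.95

    def test_ensemble_mse_not_worse_than_mean_member_mse(self, fitted):
        X, y, reg = fitted
        _, _, te = reg.splits_
        Xs = reg.ensemble_.scaling.scale_x(X[te])
        member_mses = []
        for m in reg.ensemble_.members:
            out, _ = _forward(m.weights, Xs, X.shape[1], m.hidden_size,
                              m.hidden_activation, m.output_activation)
            pred = reg.ensemble_.scaling.unscale_y(out)
            member_mses.append(np.mean((y[te] - pred) ** 2))
        ens_mse = np.mean((y[te] - reg.predict(X[te])) ** 2)
        assert ens_mse <= np.mean(member_mses) + 1e-9

    def test_reproducible_for_fixed_seed(self, fitted, study_seed7):
        X, y, reg = fitted
        reg2 = MLPEnsembleRegressor(random_state=11).fit(X, y)
        np.testing.assert_allclose(reg.predict(X[:50]), reg2.predict(X[:50]), atol=1e-6)

    def test_constant_target_predicts_the_constant(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (60, 4))
        y = np.full(60, 250.0)
        reg = MLPEnsembleRegressor(random_state=0, n_candidates=6, n_retained=5).fit(X, y)
        assert np.all(np.isnan([m.val_r2 for m in reg.ensemble_.members]))
        np.testing.assert_allclose(reg.predict(X), 250.0, atol=1e-3)
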