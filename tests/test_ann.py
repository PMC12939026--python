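import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocoflux.ann import (
    MinMaxScaler,
    MLPSurrogate,
    TrainConfig,
    purelin,
    select_best,
    split_samples,
    tansig,
    train,
    _forward,
)
from cocoflux.synth import FCDGenSpec, gen_fcd_dataset


class TestTransferFunctions:
    def test_tansig_values(self):
        assert tansig(0.0) == 0.0
        assert tansig(1.0) == pytest.approx(2.0 / (1.0 + np.exp(-2.0)) - 1.0)
        assert tansig(1.0) == pytest.approx(0.76159, abs=1e-5)

    @given(st.floats(-50, 50))
    def test_tansig_odd_and_bounded(self, n):
        assert tansig(n) == pytest.approx(-tansig(-n), abs=1e-12)
        assert -1.0 <= tansig(n) <= 1.0

    def test_purelin_identity(self):
        x = np.linspace(-5, 5, 7)
        assert np.array_equal(purelin(x), x)


class TestScaler:
    def test_extremes_map_to_unit_interval(self):
        X = np.array([[50.0, 20.0], [200.0, 40.0], [125.0, 30.0]])
        sc = MinMaxScaler.fit(X)
        Xs = sc.transform(X)
        assert Xs.min() == -1.0 and Xs.max() == 1.0
        assert np.allclose(Xs[2], [0.0, 0.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True))
    def test_round_trip(self, vals):
        X = np.array(vals).reshape(-1, 1)
        sc = MinMaxScaler.fit(X)
        assert np.allclose(sc.inverse(sc.transform(X)), X, atol=1e-9)

    def test_constant_variable_maps_to_zero(self):
        sc = MinMaxScaler.fit(np.full((5, 2), 7.0))
        assert np.all(sc.transform(np.full((3, 2), 7.0)) == 0.0)
        assert np.all(sc.inverse(np.zeros((3, 2))) == 7.0)


class TestSplit:
    def test_pilot_sizes(self):
        tr, va, te = split_samples(29, rng=0)
        assert (len(tr), len(va), len(te)) == (20, 4, 5)

    def test_small_n_apportionment(self):
        tr, va, te = split_samples(10, rng=0)
        assert (len(tr), len(va), len(te)) == (7, 1, 2)

    def test_disjoint_exhaustive_deterministic(self):
        a = split_samples(29, rng=42)
        b = split_samples(29, rng=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        allidx = np.concatenate(a)
        assert sorted(allidx) == list(range(29))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_samples(2)


class TestTraining:
    def test_known_network_recovered_unregularized(self, pilot):
        """With zero noise and no weight penalty, LM drives the training
        error of a realizable target to numerical zero."""
        rng = np.random.default_rng(123)
        theta_true = rng.uniform(-1, 1, 27)
        X, _ = pilot.samples("flux")
        # physical inputs from the pilot conditions
        P = np.array([pilot.factors[0].decode(c) for c in X[:, 0]])
        T = np.array([pilot.factors[1].decode(c) for c in X[:, 1]])
        xsc = MinMaxScaler.fit(np.column_stack([P, T]))
        Xs = xsc.transform(np.column_stack([P, T]))
        Ys, _ = _forward(theta_true, Xs)
        # build a dataset whose responses are the network's own outputs
        ds = _dataset_with_targets(pilot, Ys)
        model = train(ds, TrainConfig(reg_lambda=0.0, seed=2, max_epochs=400,
                                      patience=50))
        assert model.diagnostics.mse["train"] < 1e-6

    def test_linear_target_matches_ols(self, pilot):
        """An unregularized network on an exactly linear target agrees
        with the least-squares line on training points to within 1%."""
        X, _ = pilot.samples("flux")
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 10.0
        ds = _dataset_with_targets(pilot, np.column_stack([y, y]), scaled=False)
        model = train(ds, TrainConfig(reg_lambda=0.0, seed=4))
        P = np.array([pilot.factors[0].decode(c) for c in X[:, 0]])
        T = np.array([pilot.factors[1].decode(c) for c in X[:, 1]])
        pred = model.predict(P, T)[:, 0]
        assert np.all(np.abs(pred - y) <= 0.01 * np.abs(y))

    def test_constant_target_small_weights(self, pilot):
        X, _ = pilot.samples("flux")
        n = len(X)
        ds = _dataset_with_targets(
            pilot,
            np.column_stack([np.full(n, 500.0), np.full(n, 80.0)]),
            scaled=False,
        )
        model = train(ds, TrainConfig(reg_lambda=0.10, seed=6))
        pred = model.predict(125.0, 30.0)
        assert pred[0] == pytest.approx(500.0, abs=1.0)
        msw = np.mean(np.concatenate([
            model.W1.ravel(), model.b1, model.W2.ravel(), model.b2
        ]) ** 2)
        assert msw < 0.2

    def test_hidden_activations_bounded(self, pilot):
        model = train(pilot, TrainConfig(seed=0))
        rng = np.random.default_rng(0)
        P = rng.uniform(0, 400, 100)
        T = rng.uniform(0, 80, 100)
        Xs = model.x_scaler.transform(np.column_stack([P, T]))
        h = np.tanh(Xs @ model.W1.T + model.b1)
        assert np.all(np.abs(h) < 1.0)

    def test_zero_weight_network_outputs_bias(self, pilot):
        model = train(pilot, TrainConfig(seed=0))
        model.W1[:] = 0.0
        model.W2[:] = 0.0
        model.b1[:] = 0.0
        model.b2[:] = np.array([0.25, -0.5])
        out = model.forward_scaled(np.array([[0.3, -0.7]]))
        assert np.allclose(out, [0.25, -0.5])


class TestSelection:
    def test_single_restart_equals_train(self, pilot):
        cfg = TrainConfig(seed=9, n_restarts=1)
        best = select_best(pilot, cfg)
        solo = train(pilot, cfg, rng=np.random.default_rng(
            np.random.SeedSequence(9).spawn(1)[0]))
        assert np.allclose(best.W1, solo.W1)

    def test_returned_validation_mse_is_minimum(self, pilot):
        best = select_best(pilot, TrainConfig(seed=1, n_restarts=5))
        vals = [r["val_mse"] for r in best.diagnostics.restarts]
        assert best.diagnostics.mse["validation"] == pytest.approx(min(vals))

    def test_center_prediction_near_published(self, pilot):
        """Best-of-20 restart training lands the center-point flux within
        5% of the published network's 659.19."""
        model = select_best(pilot, TrainConfig(seed=0, n_restarts=20))
        flux, _ = model.predict_physical(125.0, 30.0)
        assert flux == pytest.approx(659.19, rel=0.05)

    def test_setpoint_prediction_envelope(self, pilot):
        model = select_best(pilot, TrainConfig(seed=0, n_restarts=20))
        flux, fi = model.predict_physical(75.0, 30.0)
        assert 590.0 <= flux <= 680.0
        assert 75.0 <= fi <= 90.0

    def test_json_round_trip(self, pilot, tmp_path):
        model = select_best(pilot, TrainConfig(seed=3, n_restarts=2))
        p = tmp_path / "ann.json"
        model.save_json(p)
        back = MLPSurrogate.load_json(p)
        assert back.predict_physical(100.0, 25.0) == pytest.approx(
            model.predict_physical(100.0, 25.0)
        )


def _dataset_with_targets(pilot, Y, scaled=True):
    """Clone the pilot design geometry with externally supplied targets.

    When ``scaled`` the targets are treated as already in [-1, 1]-ish
    network space and are linearly mapped to plausible physical ranges.
    """
    import copy

    ds = copy.deepcopy(pilot)
    Y = np.asarray(Y, dtype=float)
    if scaled:
        Y = np.column_stack([
            500.0 + 200.0 * Y[:, 0],
            85.0 + 10.0 * Y[:, 1],
        ])
    i = 0
    for cond in ds.conditions:
        n = cond.n_replicates
        cond.replicate_responses["flux"] = Y[i:i + n, 0].tolist()
        cond.replicate_responses["fouling_index"] = Y[i:i + n, 1].tolist()
        i += n
    return ds
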