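import numpy as np
import pytest

from ivimdnn.core import AcquisitionScheme, IVIMParams, ParamRanges, signal_vector
from ivimdnn.dnn import (EarlyStopping, MLP, NetworkConfig, ABLATION_ARMS,
                         TrainedModel, TrainingConfig, predict,
                         run_ablation_grid, train, train_on_phantoms)
from ivimdnn.phantom import SimulationGrid, generate_grid

SMALL_NET = NetworkConfig(n_inputs=18, hidden_layers=2, hidden_width=8)


def _noiseless_dataset(n=200, seed=3):
    rng = np.random.default_rng(seed)
    ranges = ParamRanges()
    D = rng.uniform(*ranges.D, n)
    f = rng.uniform(*ranges.f, n)
    Ds = rng.uniform(*ranges.Dstar, n)
    sig = signal_vector(IVIMParams(D=D, f=f, Dstar=Ds), AcquisitionScheme(),
                        S0=rng.uniform(0.5, 1.5, n))
    return sig, np.column_stack([D, f, Ds])


class TestMLP:
    def test_jacobian_matches_finite_differences(self):
        net = MLP(NetworkConfig(n_inputs=4, hidden_layers=2, hidden_width=3))
        rng = np.random.default_rng(0)
        net.init_weights(rng)
        X = rng.standard_normal((5, 4))
        J = net.jacobian(X)
        theta = net.get_flat()
        eps = 1e-6
        for pi in rng.choice(net.n_params, 15, replace=False):
            step = np.zeros_like(theta)
            step[pi] = eps
            net.set_flat(theta + step)
            up = net.forward(X)
            net.set_flat(theta - step)
            dn = net.forward(X)
            net.set_flat(theta)
            assert np.allclose(J[:, :, pi], (up - dn) / (2 * eps), atol=1e-5)

    def test_gradient_matches_jacobian_chain(self):
        net = MLP(NetworkConfig(n_inputs=4, hidden_layers=2, hidden_width=3))
        rng = np.random.default_rng(1)
        net.init_weights(rng)
        X = rng.standard_normal((7, 4))
        Y = rng.standard_normal((7, 3))
        loss, g = net.gradient(X, Y)
        J = net.jacobian(X).reshape(-1, net.n_params)
        r = (net.forward(X) - Y).ravel()
        assert np.allclose(g, 2.0 * J.T @ r / r.size, atol=1e-10)


class TestEarlyStopping:
    def test_stops_after_patience_consecutive_failures(self):
        es = EarlyStopping(patience=6)
        theta = np.zeros(2)
        assert not es.check(1.0, theta)
        outcomes = [es.check(1.0 + 0.1 * k, theta) for k in range(1, 7)]
        assert outcomes == [False] * 5 + [True]

    def test_improvement_resets_counter_and_keeps_best(self):
        es = EarlyStopping(patience=2)
        es.check(1.0, np.array([1.0]))
        es.check(2.0, np.array([2.0]))
        assert not es.check(0.5, np.array([3.0]))
        assert es.best_loss == 0.5 and es.best_theta[0] == 3.0
        assert es.fails == 0


class TestTrain:
    def test_noiseless_toy_converges(self):
        """200 noiseless voxels, small LM-trained net: validation MSE on
        standardized targets < 1e-2 within 500 iterations."""
        sig, tgt = _noiseless_dataset()
        model = train(sig, tgt, SMALL_NET,
                      TrainingConfig(optimizer="lm", max_iterations=500, seed=0))
        assert model.metadata["final_val_mse"] < 1e-2
        assert model.metadata["stop_reason"] in (
            "min_gradient", "max_iterations", "patience_exhausted")

    def test_lm_training_loss_monotone(self):
        """The damped second-order optimizer only accepts improving steps."""
        sig, tgt = _noiseless_dataset()
        model = train(sig, tgt, SMALL_NET,
                      TrainingConfig(optimizer="lm", max_iterations=100, seed=0))
        assert np.all(np.diff(model.metadata["train_loss"]) <= 0)

    @pytest.mark.parametrize("optimizer", ["lm", "adam"])
    def test_deterministic_given_seed(self, optimizer):
        sig, tgt = _noiseless_dataset(n=120)
        cfg = TrainingConfig(optimizer=optimizer, max_iterations=20, seed=7)
        a = train(sig, tgt, SMALL_NET, cfg)
        b = train(sig, tgt, SMALL_NET, cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            train(np.empty((0, 9)), np.empty((0, 3)))

    def test_predicted_d_median_within_physical_range(self):
        sig, tgt = _noiseless_dataset()
        model = train(sig, tgt, SMALL_NET,
                      TrainingConfig(optimizer="lm", max_iterations=200, seed=0))
        lo, hi = ParamRanges().D
        med = np.median(model.predict_signals(sig)[:, 0])
        assert lo <= med <= hi

    def test_more_training_data_does_not_hurt(self):
        """Monotone learning sanity: 10x more noiseless voxels should not
        raise the held-out median absolute error materially."""
        ho_sig, ho_tgt = _noiseless_dataset(n=300, seed=99)
        errs = []
        for n in (300, 3000):
            sig, tgt = _noiseless_dataset(n=n, seed=5)
            model = train(sig, tgt, SMALL_NET,
                          TrainingConfig(optimizer="lm", max_iterations=150, seed=1))
            pred = model.predict_signals(ho_sig)
            errs.append(np.median(np.abs(pred - ho_tgt) / ho_tgt, axis=0))
        assert np.all(errs[1] <= errs[0] * 1.5 + 1e-3)


@pytest.fixture(scope="module")
def toy_model():
    sig, tgt = _noiseless_dataset(n=400, seed=2)
    return train(sig, tgt, SMALL_NET,
                 TrainingConfig(optimizer="lm", max_iterations=300, seed=0))


class TestPredict:
    def test_all_background_mask_gives_nan_maps(self, toy_model):
        vol = np.ones((4, 4, 9))
        d, f, ds = predict(toy_model, vol, np.zeros((4, 4), dtype=bool))
        assert np.all(np.isnan(d)) and np.all(np.isnan(f)) and np.all(np.isnan(ds))

    def test_batch_order_invariance(self, toy_model):
        sig, _ = _noiseless_dataset(n=50, seed=8)
        single = toy_model.predict_signals(sig[10:11])
        batched = toy_model.predict_signals(sig)
        assert np.allclose(single[0], batched[10], rtol=1e-12)

    def test_b_value_mismatch_mentions_retraining(self, toy_model):
        with pytest.raises(ValueError, match="retrain"):
            toy_model.predict_signals(np.ones((3, 7)))

    def test_noiseless_phantom_d_accuracy(self, toy_model, template, scheme,
                                          ranges):
        """A converged model keeps the median relative D error below 5% on
        noiseless phantom voxels (consistency with the LSQ oracle regime)."""
        from ivimdnn.phantom import generate_phantom

        inst = generate_phantom(template, scheme, ranges, 100,
                                np.random.default_rng(21))
        d, f, ds = predict(toy_model, inst.noiseless, inst.foreground)
        fg = inst.foreground
        rel = np.abs(d[fg] - inst.truth_D[fg]) / inst.truth_D[fg]
        assert np.median(rel) < 0.05

    def test_model_file_round_trip(self, toy_model, tmp_path):
        p = toy_model.save(tmp_path / "m.ivimdnn")
        reread = TrainedModel.load(p)
        sig, _ = _noiseless_dataset(n=20, seed=4)
        assert np.array_equal(toy_model.predict_signals(sig),
                              reread.predict_signals(sig))

    def test_sklearn_cross_check(self):
        """An independently trained scikit-learn MLP on the same features
        reaches the same accuracy regime on noiseless data — the numpy
        implementation is not an outlier."""
        from sklearn.neural_network import MLPRegressor

        from ivimdnn.features import (FeatureConfig, TargetStandardizer,
                                      build_features, fit_feature_scaling)

        sig, tgt = _noiseless_dataset(n=2000, seed=6)
        cfg = fit_feature_scaling(sig, FeatureConfig())
        X = build_features(sig, cfg)
        std = TargetStandardizer.fit(tgt)
        ref = MLPRegressor(hidden_layer_sizes=(8, 8), activation="tanh",
                           max_iter=2000, random_state=0, tol=1e-7)
        ref.fit(X, std.standardize(tgt))
        ref_mse = np.mean((ref.predict(X) - std.standardize(tgt)) ** 2)
        ours = train(sig, tgt, SMALL_NET,
                     TrainingConfig(optimizer="adam", max_iterations=300,
                                    batch_size=128, seed=0))
        assert ours.metadata["final_val_mse"] < max(5 * ref_mse, 1e-2)


class TestAblationGrid:
    def test_five_arms_produced_by_name_with_shared_split(self):
        grid = SimulationGrid(snr_levels=(25, 100), phantoms_per_snr=2,
                              master_seed=13)
        phantoms = [inst for _, inst in generate_grid(grid)]
        tr_cfg = TrainingConfig(optimizer="adam", max_iterations=3, seed=0)
        res = run_ablation_grid(ABLATION_ARMS, phantoms[:2], phantoms[2:],
                                training=tr_cfg, hidden_width=4, max_voxels=2000)
        assert set(res) == set(ABLATION_ARMS)
        metas = [res[k]["model"].metadata for k in res]
        assert len({m["n_training_voxels"] for m in metas}) == 1
        assert res["h3-9in-raw"]["model"].standardizer.enabled is False
        assert res["h3-18in-std"]["model"].network.n_inputs == 18
        assert res["h4-9in-std"]["model"].network.hidden_layers == 4
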