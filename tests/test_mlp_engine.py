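"""Network forward pass, losses, training behaviour and prediction contract."""

import math

import numpy as np
import pytest

from capmech.membrane_laws import FlowCondition, LawKind
from capmech.profile_synthesis import Dataset, LabelledSample
from capmech.mlp_engine import (
    NetworkParameters,
    TrainingConfig,
    _Net,
    forward,
    losses,
    predict,
    predict_batch,
    softmax,
    train,
)


def _toy_dataset(n=40, n_features=8, seed=0, separable=True):
    """Linearly structured toy set: class from sign pattern, Ca from sums."""
    rng = np.random.default_rng(seed)
    samples = []
    kinds = [LawKind.NEO_HOOKEAN, LawKind.SKALAK, LawKind.HOOKE]
    for i in range(n):
        k = i % 3
        x = rng.normal(size=n_features) * 0.1
        if separable:
            x[k] += 3.0
        ca_ks = 0.02 + 0.03 * rng.random()
        ca_gs = 0.05 + 0.1 * rng.random()
        x[3] += 10 * ca_ks
        x[4] += 5 * ca_gs
        samples.append(LabelledSample(vector=x, law_kind=kinds[k],
                                      ca_ks=ca_ks, ca_gs=ca_gs))
    return Dataset(samples=samples, manifest={"seed": seed})


class TestSoftmaxAndForward:
    def test_softmax_normalised_and_stable(self, rng):
        for _ in range(20):
            logits = rng.normal(scale=50.0, size=(4, 3))
            p = softmax(logits)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(p >= 0)

    def test_softmax_closed_form(self):
        p = softmax(np.array([math.log(2.0), 0.0, 0.0]))
        np.testing.assert_allclose(p, [0.5, 0.25, 0.25], atol=1e-12)

    def test_zero_weight_network_is_uniform(self):
        rng = np.random.default_rng(0)
        net = _Net(6, [4], 3, 2, rng)
        for w in net.params():
            w[...] = 0.0
        params = NetworkParameters(
            nets=[net], y_mean=np.zeros(2), y_std=np.ones(2), n_in=6,
            hidden=(4,), shared_trunk=True, dropout=0.0, trained=True,
        )
        probs, reg = forward(params, np.zeros(6))
        np.testing.assert_allclose(probs[0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(reg[0], net.br, atol=1e-12)

    def test_toy_network_matches_pencil_arithmetic(self):
        """2-2-1 network with hand-set weights against manual evaluation."""
        rng = np.random.default_rng(0)
        net = _Net(2, [2], 3, 1, rng)
        net.W[0][...] = [[1.0, -1.0], [0.5, 2.0]]
        net.gamma[0][...] = 1.0
        net.beta[0][...] = [0.1, -0.2]
        net.run_mean[0][...] = 0.0
        net.run_var[0][...] = 1.0 - 1e-5  # unit inverse std with the BN epsilon
        net.Wc[...] = 0.0
        net.bc[...] = 0.0
        net.Wr[...] = [[1.0], [1.0]]
        net.br[...] = 0.5
        x = np.array([2.0, 1.0])
        # dense: [2*1+1*0.5, 2*(-1)+1*2] = [2.5, 0]; bn: +[0.1, -0.2]
        # relu: [2.6, 0]; reg: 2.6 + 0 + 0.5 = 3.1
        _, reg, _ = net.forward(x[None], training=False)
        assert reg[0, 0] == pytest.approx(3.1, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        ds = _toy_dataset()
        params = train(ds, TrainingConfig(seed=0, max_epochs=3, batch_size=16,
                                          plateau_patience=2, stop_patience=3))
        with pytest.raises(ValueError, match="feature length"):
            forward(params, np.zeros(5))


class TestLosses:
    def test_perfect_classification_has_zero_loss(self):
        z = np.array([[1.0, 0.0, 0.0]])
        p = np.array([[1.0, 0.0, 0.0]])
        l_cls, _ = losses(p, np.zeros((1, 2)), z, np.zeros((1, 2)))
        assert l_cls == pytest.approx(0.0, abs=1e-9)

    def test_perfect_regression_has_zero_loss(self):
        y = np.array([[0.3, -1.2]])
        _, l_reg = losses(np.full((1, 3), 1 / 3), y, np.eye(3)[:1], y)
        assert l_reg == pytest.approx(0.0)

    def test_uniform_prediction_cross_entropy_is_ln3(self):
        p = np.full((5, 3), 1 / 3)
        z = np.eye(3)[[0, 1, 2, 0, 1]]
        l_cls, _ = losses(p, np.zeros((5, 2)), z, np.zeros((5, 2)))
        assert l_cls == pytest.approx(math.log(3.0), abs=1e-12)

    def test_zero_probability_floored(self):
        p = np.array([[0.0, 1.0, 0.0]])
        z = np.array([[1.0, 0.0, 0.0]])
        l_cls, _ = losses(p, np.zeros((1, 2)), z, np.zeros((1, 2)))
        assert np.isfinite(l_cls)


class TestTraining:
    CFG = dict(batch_size=16, plateau_patience=30, stop_patience=80,
               max_epochs=300, dropout=0.0)

    def test_overfits_separable_toy_set(self):
        ds = _toy_dataset(separable=True)
        params = train(ds, TrainingConfig(seed=1, **self.CFG))
        X, z, _ = ds.matrices()
        probs, _ = predict_batch(params, X)
        assert np.mean(np.argmax(probs, axis=1) == z) == 1.0

    def test_training_is_deterministic(self):
        ds = _toy_dataset()
        cfg = TrainingConfig(seed=3, **self.CFG)
        a = train(ds, cfg)
        b = train(ds, cfg)
        assert a.manifest["best_val_loss"] == b.manifest["best_val_loss"]
        for wa, wb in zip(a.nets[0].params(), b.nets[0].params()):
            np.testing.assert_array_equal(wa, wb)

    def test_loss_decreases_from_first_epoch(self):
        ds = _toy_dataset()
        params = train(ds, TrainingConfig(seed=2, **self.CFG))
        hist = params.history
        best = min(h["train_loss"] for h in hist)
        assert best < hist[0]["train_loss"]

    def test_split_networks_supported(self):
        ds = _toy_dataset()
        params = train(ds, TrainingConfig(seed=4, shared_trunk=False, **self.CFG))
        assert len(params.nets) == 2
        X, z, y = ds.matrices()
        probs, ca = predict_batch(params, X)
        assert probs.shape == (len(ds), 3) and ca.shape == (len(ds), 2)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(Dataset(samples=[], manifest={}), TrainingConfig())


@pytest.fixture(scope="module")
def trained():
    ds = _toy_dataset(n=60, seed=5)
    return ds, train(ds, TrainingConfig(seed=5, batch_size=16, dropout=0.0,
                                        plateau_patience=30, stop_patience=80,
                                        max_epochs=300))


class TestPredict:

    def test_argmax_rule_and_positive_ca(self, trained):
        from capmech.membrane_laws import LAW_ORDER

        ds, params = trained
        pred = predict(params, ds.samples[0].vector)
        assert pred.law_kind is LAW_ORDER[int(np.argmax(pred.probs))]
        assert pred.ca_ks > 0 and pred.ca_gs > 0
        assert pred.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_moduli_attached_with_flow(self, trained):
        ds, params = trained
        flow = FlowCondition(mu=1.0, U=1e-3)
        pred = predict(params, ds.samples[0].vector, flow)
        assert pred.Ks == pytest.approx(1e-3 / pred.ca_ks)
        assert pred.Gs == pytest.approx(1e-3 / pred.ca_gs)

    def test_prediction_is_pure_function(self, trained):
        ds, params = trained
        x = ds.samples[1].vector
        a = predict(params, x)
        b = predict(params, x)
        np.testing.assert_array_equal(a.probs, b.probs)
        assert (a.ca_ks, a.ca_gs) == (b.ca_ks, b.ca_gs)

    def test_untrained_parameters_flagged(self):
        rng = np.random.default_rng(0)
        params = NetworkParameters(
            nets=[_Net(4, [3], 3, 2, rng)], y_mean=np.zeros(2), y_std=np.ones(2),
            n_in=4, hidden=(3,), shared_trunk=True, dropout=0.0, trained=False,
        )
        with pytest.raises(ValueError, match="untrained"):
            predict(params, np.zeros(4))

    def test_json_roundtrip_preserves_predictions(self, trained, tmp_path):
        ds, params = trained
        path = tmp_path / "model.json"
        params.to_json(path)
        back = NetworkParameters.from_json(path)
        x = ds.samples[2].vector
        a, b = predict(params, x), predict(back, x)
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)
        assert a.ca_ks == pytest.approx(b.ca_ks, abs=1e-12)
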