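"""Losses, network construction, prediction contracts, attention
extraction, and training behaviour of the model zoo."""

import numpy as np
import pytest

from trapod.models import (
    FocalLossParams,
    ModelConfig,
    PodModel,
    build_hybrid,
    build_model,
    extract_attention,
    focal_loss,
    predict,
    weighted_ce,
)
from trapod.nn import Tensor
from trapod.nn.networks import MLPNet, TransformerNet


class TestLosses:
    def test_focal_at_half_is_log_two(self):
        # gamma=0, alpha=1, p_t=0.5 -> -ln(0.5)
        loss = focal_loss(np.array([0.5]), np.array([1]),
                          FocalLossParams(gamma=0.0, alpha=1.0))
        assert loss == pytest.approx(0.6931471805599453, abs=1e-12)

    def test_perfect_prediction_zero_loss(self):
        loss = focal_loss(np.array([1.0 - 1e-16]), np.array([1]),
                          FocalLossParams(gamma=2.0, alpha=1.0))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_focal_hand_value(self):
        # gamma=2, alpha=0.25, p_t=0.9 -> 0.25 * 0.01 * (-ln 0.9)
        loss = focal_loss(np.array([0.9]), np.array([1]),
                          FocalLossParams(gamma=2.0, alpha=0.25))
        assert loss == pytest.approx(0.25 * 0.01 * -np.log(0.9), abs=1e-12)
        assert loss == pytest.approx(2.634e-4, rel=1e-3)

    def test_gamma_zero_reduces_to_weighted_ce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 20)
        y = rng.integers(0, 2, 20)
        # alpha=w/(1+w) normalization: weighted CE with pos_weight w equals
        # (1+w) * focal(alpha=w/(1+w), gamma=0)
        w = 3.0
        fl = focal_loss(p, y, FocalLossParams(gamma=0.0, alpha=w / (1 + w)))
        ce = weighted_ce(p, y, pos_weight=w)
        assert ce == pytest.approx((1 + w) * fl, abs=1e-12)

    def test_weighted_ce_unit_weight_is_plain_ce(self):
        p = np.array([0.8, 0.3])
        y = np.array([1, 0])
        expected = np.mean([-np.log(0.8), -np.log(0.7)])
        assert weighted_ce(p, y, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_two_sample_batch_hand_computed(self):
        p = np.array([0.7, 0.2])
        y = np.array([1, 0])
        expected = np.mean([-2.0 * np.log(0.7), -np.log(0.8)])
        assert weighted_ce(p, y, 2.0) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_probability_clipped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="trapod.models"):
            loss = focal_loss(np.array([1.0]), np.array([1]),
                              FocalLossParams(gamma=0.0, alpha=1.0))
        assert np.isfinite(loss)
        assert "clipped" in caplog.text


@pytest.fixture
def seq_batch():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((8, 10, 4))  # m x n x k
    y = np.array([0, 1, 0, 1, 0, 0, 1, 0])
    return X, y


class TestBuildAndPredict:
    @pytest.mark.parametrize("variant", ["MLP_TAB_P", "LSTM_SEQ", "TRAN_SEQ"])
    def test_one_score_per_surgery_in_unit_interval(self, variant, seq_batch):
        X, _ = seq_batch
        if variant.startswith("MLP"):
            shapes, data = {"n_tabular": 6}, np.random.default_rng(0).random((8, 6))
        else:
            shapes, data = {"n_channels": 4, "n_steps": 10}, X
        config = ModelConfig(variant=variant, seed=1)
        net = build_model(config, shapes)
        pred = predict(net, config, data)
        assert pred.scores.shape == (8,)
        assert ((pred.scores >= 0) & (pred.scores <= 1)).all()

    def test_eval_deterministic(self, seq_batch):
        X, _ = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 10})
        a = predict(net, config, X).scores
        b = predict(net, config, X).scores
        np.testing.assert_array_equal(a, b)

    def test_attention_rows_sum_to_one(self, seq_batch):
        X, _ = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 10})
        net(Tensor(X, requires_grad=False))
        attn = net.blocks[-1].last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_parameter_count_pure_function_of_config(self):
        config = ModelConfig(variant="TRAN_SEQ", seed=5)
        shapes = {"n_channels": 4, "n_steps": 10}
        a = build_model(config, shapes).describe()
        b = build_model(config, shapes).describe()
        assert a == b and a["total"] > 0

    def test_shape_mismatch_reported(self, seq_batch):
        X, _ = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 8})
        with pytest.raises(ValueError, match="time steps"):
            predict(net, config, X)


class TestHybrid:
    def _nets(self):
        rng = np.random.default_rng(0)
        seq = TransformerNet(rng, d_in=3, n_steps=5, d_model=8, head=[4])
        tab = MLPNet(rng, 6, [4])
        return build_hybrid(seq, tab, seed=0)

    def test_combiner_projections(self):
        net = self._nets()
        rng = np.random.default_rng(1)
        x_seq = Tensor(rng.standard_normal((5, 5, 3)), requires_grad=False)
        x_tab = Tensor(rng.standard_normal((5, 6)), requires_grad=False)
        z_seq = net.seq(x_seq).data
        z_tab = net.tab(x_tab).data
        net.combine.W.data = np.array([[1.0], [0.0]])
        net.combine.b.data = np.array([0.0])
        np.testing.assert_allclose(net((x_seq, x_tab)).data, z_seq, atol=1e-12)
        net.combine.W.data = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(net((x_seq, x_tab)).data, z_tab, atol=1e-12)

    def test_gradient_reaches_both_branches(self):
        net = self._nets()
        rng = np.random.default_rng(2)
        x_seq = Tensor(rng.standard_normal((4, 5, 3)), requires_grad=False)
        x_tab = Tensor(rng.standard_normal((4, 6)), requires_grad=False)
        out = net((x_seq, x_tab))
        loss = (out * out).mean()
        net.zero_grad()
        loss.backward()
        g_seq = net.seq.named_parameters()["proj.W"].grad
        g_tab = net.tab.named_parameters()["hidden0.W"].grad
        assert g_seq is not None and np.abs(g_seq).max() > 0
        assert g_tab is not None and np.abs(g_tab).max() > 0

    def test_gradient_matches_finite_difference(self):
        net = self._nets()
        rng = np.random.default_rng(4)
        x_seq = rng.standard_normal((3, 5, 3))
        x_tab = rng.standard_normal((3, 6))
        y = np.array([1.0, 0.0, 1.0])

        def loss_value():
            out = net((Tensor(x_seq, requires_grad=False),
                       Tensor(x_tab, requires_grad=False)))
            p = out.sigmoid().clip(1e-12, 1 - 1e-12)
            pt = p * y + (1.0 - p) * (1.0 - y)
            return (pt.log() * -1.0).mean()

        loss = loss_value()
        net.zero_grad()
        loss.backward()
        p = net.tab.named_parameters()["hidden0.W"]
        auto = p.grad[0, 0]
        eps = 1e-6
        p.data[0, 0] += eps
        up = loss_value().item()
        p.data[0, 0] -= 2 * eps
        down = loss_value().item()
        p.data[0, 0] += eps
        assert auto == pytest.approx((up - down) / (2 * eps), abs=1e-6)


class TestAttentionExtraction:
    def test_uniform_attention_gives_flat_profile(self, seq_batch):
        X, _ = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 10})
        # zero the query/key projections -> equal logits -> uniform softmax
        for name in ("Wq", "Wk"):
            layer = getattr(net.blocks[-1], name)
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        att = extract_attention(net, config, X)
        np.testing.assert_allclose(att.per_time_mean, 1.0 / 10, atol=1e-12)

    def test_saliency_nonnegative_and_named(self, seq_batch):
        X, _ = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 10})
        att = extract_attention(net, config, X)
        assert (att.saliency >= 0).all()
        assert att.saliency.shape == (4, 10)

    def test_channel_permutation_permutes_saliency_rows(self, seq_batch):
        X, _ = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 10})
        att = extract_attention(net, config, X)
        perm = [2, 0, 3, 1]
        net.proj.W.data = net.proj.W.data[perm]
        att_p = extract_attention(net, config, X[:, :, perm])
        np.testing.assert_allclose(att_p.saliency, att.saliency[perm], atol=1e-9)

    def test_non_attention_model_rejected(self):
        config = ModelConfig(variant="LSTM_SEQ", seed=1)
        net = build_model(config, {"n_channels": 4, "n_steps": 10})
        with pytest.raises(ValueError, match="attention"):
            extract_attention(net, config, np.zeros((2, 10, 4)))


class TestTraining:
    @pytest.mark.parametrize("variant", ["MLP_TAB_P", "LSTM_SEQ", "TRAN_SEQ",
                                         "MLP_TRAN_SEQTAB"])
    def test_overfits_toy_set(self, variant):
        """Capacity sanity check: every variant can drive training AUROC
        above 0.95 on a 50-surgery toy problem."""
        from trapod.evaluate import compute_metrics

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 50)
        X_seq = rng.standard_normal((50, 10, 3)) + y[:, None, None]
        X_tab = rng.standard_normal((50, 5)) + y[:, None]
        if variant == "MLP_TAB_P":
            data = X_tab
        elif variant in ("LSTM_SEQ", "TRAN_SEQ"):
            data = X_seq
        else:
            data = (X_seq, X_tab)
        config = ModelConfig(variant=variant, learning_rate=3e-3,
                             batch_size=16, seed=2)
        model = PodModel(data, y, config)
        res = model.fit(max_epochs=200)
        auroc = compute_metrics(res.predict(data).scores, y).auroc
        assert auroc > 0.95

    def test_early_stopping_on_flat_loss(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 40)
        X = rng.standard_normal((40, 6))
        config = ModelConfig(variant="MLP_TAB_P", learning_rate=0.0, seed=1)
        model = PodModel(X, y, config)
        res = model.fit(val_inputs=X, val_labels=y, max_epochs=100, patience=10)
        # zero learning rate -> loss flat from epoch 1 -> stop at 1 + patience
        assert len(res.log.epochs) == 11
        assert res.log.stopped_early

    def test_restored_weights_reproduce_best_val_loss(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 60)
        X = rng.standard_normal((60, 6)) + 0.3 * y[:, None]
        Xv = rng.standard_normal((30, 6))
        yv = rng.integers(0, 2, 30)
        config = ModelConfig(variant="MLP_TAB_P", learning_rate=1e-2, seed=1)
        model = PodModel(X, y, config)
        res = model.fit(val_inputs=Xv, val_labels=yv, max_epochs=30, patience=5)
        reevaluated = model._eval_loss(Xv, yv)
        assert reevaluated == pytest.approx(res.best_val_loss, abs=1e-12)

    def test_empty_validation_rejected(self):
        rng = np.random.default_rng(7)
        model = PodModel(rng.random((10, 3)), rng.integers(0, 2, 10),
                         ModelConfig(variant="MLP_TAB_P", seed=0))
        with pytest.raises(ValueError, match="validation"):
            model.fit(val_inputs=np.zeros((0, 3)), val_labels=np.zeros(0))

    def test_checkpoint_roundtrip(self, tmp_path, seq_batch):
        from trapod.models import PodResults

        X, y = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=3)
        model = PodModel(X, y.astype(float), config)
        res = model.fit(max_epochs=2)
        before = res.predict(X).scores
        path = tmp_path / "model.zip"
        res.save(path)
        net, cfg = PodResults.load_network(path)
        after = predict(net, cfg, X).scores
        np.testing.assert_allclose(before, after, atol=1e-15)

    def test_summary_mentions_variant_and_parameters(self, seq_batch):
        X, y = seq_batch
        config = ModelConfig(variant="TRAN_SEQ", seed=3)
        res = PodModel(X, y.astype(float), config).fit(max_epochs=1)
        text = res.summary()
        assert "TRAN_SEQ" in text and "parameters" in text
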