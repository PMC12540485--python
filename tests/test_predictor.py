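"""The attention-BiLSTM predictor: encoding, forward contracts, metrics,
cross-validation, and learning on a small planted-structure dataset."""

import numpy as np
import pytest

from affectpath.nn import positional_encoding
from affectpath.predictor import (
    AttentionBiLSTMNet,
    Metrics,
    ModelConfig,
    NextVisitModel,
    PredictionResult,
    compute_metrics,
    encode_batch,
    evaluate,
    load_net,
    model_forward,
    save_net,
    train_model,
)
from affectpath.types import GraphVertex, Quadrant, TrajectoryMatrix


def _sample(user, rows, area, quadrant=Quadrant.I):
    return TrajectoryMatrix(user_id=user, rows=np.asarray(rows, dtype=float),
                            target=GraphVertex(area, quadrant))


def _toy_dataset(rng, n=60, d=8, n_areas=3):
    """Planted rule: the target is determined by the final step's archetype."""
    arch = rng.normal(size=(n_areas, d))
    samples = []
    for k in range(n):
        area = int(k % n_areas)
        m = int(rng.integers(2, 6))
        rows = rng.normal(scale=0.1, size=(m, d)) + arch[area]
        samples.append(_sample(f"u{k % 10}", rows, area, Quadrant((area % 4) + 1)))
    return samples


class TestPositionalEncoding:
    def test_closed_form(self):
        d = 8
        pe = positional_encoding(4, d)
        for pos in range(4):
            for i in range(d // 2):
                angle = pos / 10000 ** (2 * i / d)
                assert pe[pos, 2 * i] == pytest.approx(np.sin(angle), abs=1e-12)
                assert pe[pos, 2 * i + 1] == pytest.approx(np.cos(angle), abs=1e-12)

    def test_position_zero_rows_and_bounds(self):
        pe = positional_encoding(30, 16)
        np.testing.assert_allclose(pe[0, 0::2], 0.0, atol=1e-12)
        np.testing.assert_allclose(pe[0, 1::2], 1.0, atol=1e-12)
        assert (np.abs(pe) <= 1.0).all()


class TestForward:
    CFG = ModelConfig(n_areas=5, d_model=8, n_heads=2, lstm_hidden=6,
                      fc_hidden=16, epochs=1, seed=0, max_seq_len=10)

    def test_probabilities_sum_to_one(self, rng):
        net = AttentionBiLSTMNet(self.CFG)
        res = model_forward(net, rng.normal(size=(4, 8)))
        assert res.area_probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.quadrant_probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert (res.area_probs >= 0).all()

    def test_single_area_class_is_certain(self, rng):
        cfg = ModelConfig(n_areas=1, d_model=8, n_heads=2, lstm_hidden=4,
                          fc_hidden=8, seed=0)
        net = AttentionBiLSTMNet(cfg)
        res = model_forward(net, rng.normal(size=(3, 8)))
        np.testing.assert_allclose(res.area_probs, [1.0])

    def test_padding_does_not_change_output(self, rng):
        """Front-padding a batch must leave a short sequence's logits intact."""
        net = AttentionBiLSTMNet(self.CFG)
        short = rng.normal(size=(3, 8))
        long = rng.normal(size=(9, 8))
        x1, m1 = encode_batch([short], net.config)
        la1, lq1 = net.forward(x1, m1)
        x2, m2 = encode_batch([short, long], net.config)
        la2, lq2 = net.forward(x2, m2)
        np.testing.assert_allclose(la1.data[0], la2.data[0], atol=1e-5)
        np.testing.assert_allclose(lq1.data[0], lq2.data[0], atol=1e-5)

    def test_empty_sequence_errors(self):
        net = AttentionBiLSTMNet(self.CFG)
        with pytest.raises(ValueError):
            encode_batch([np.zeros((0, 8))], net.config)

    def test_parameter_budget_at_default_sizes(self):
        net = AttentionBiLSTMNet(ModelConfig(n_areas=100))
        assert 470_000 * 0.7 <= net.n_parameters() <= 470_000 * 1.3

    def test_save_load_roundtrip(self, rng, tmp_path):
        net = AttentionBiLSTMNet(self.CFG)
        save_net(net, tmp_path / "m.npz")
        back = load_net(tmp_path / "m.npz")
        rows = rng.normal(size=(4, 8))
        np.testing.assert_array_equal(model_forward(net, rows).area_probs,
                                      model_forward(back, rows).area_probs)


class TestTraining:
    def test_loss_decreases_on_toy_set(self, rng):
        data = _toy_dataset(rng, n=50)
        cfg = ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                          fc_hidden=32, epochs=10, batch_size=16, seed=1)
        res = train_model(data, cfg)
        losses = [h["train_loss"] for h in res.history]
        assert losses[-1] < losses[0]
        # broadly non-increasing: each epoch is no worse than 1.05x the best so far
        best = losses[0]
        for loss in losses[1:]:
            assert loss <= 1.05 * best + 1e-9
            best = min(best, loss)

    def test_learns_planted_rule(self, rng):
        data = _toy_dataset(rng, n=120)
        cfg = ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                          fc_hidden=32, epochs=30, batch_size=16, seed=1)
        res = train_model(data, cfg)
        assert res.metrics.joint_accuracy >= 0.9

    def test_seeded_determinism_of_fit(self, rng):
        data = _toy_dataset(rng, n=30)
        cfg = ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                          fc_hidden=16, epochs=3, batch_size=8, seed=7)
        m1 = train_model(data, cfg).metrics
        m2 = train_model(data, cfg).metrics
        assert m1.to_dict() == m2.to_dict()

    def test_joint_head_variant_runs(self, rng):
        data = _toy_dataset(rng, n=30)
        cfg = ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                          fc_hidden=16, epochs=2, batch_size=8, seed=0, joint_head=True)
        res = train_model(data, cfg)
        p = res.predict(data[0].rows)
        assert p.area_probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_summary_mentions_key_quantities(self, rng):
        res = train_model(_toy_dataset(rng, n=30),
                          ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                                      fc_hidden=16, epochs=2, batch_size=8, seed=0))
        s = res.summary()
        assert "joint accuracy" in s and "trainable parameters" in s


class TestMetrics:
    def test_perfect_predictions_score_one(self):
        a = np.array([0, 1, 2, 3])
        q = np.array([0, 1, 2, 3])
        lengths = np.array([10, 20, 30, 50])
        m = compute_metrics(a, a, q, q, lengths, n_areas=4)
        assert m.joint_accuracy == 1.0 and m.area_f1 == 1.0
        assert all(v == 1.0 for v in m.per_quadrant_area_accuracy.values())

    def test_all_one_class_predictor_on_balanced_set(self):
        # 4 balanced classes, everything predicted as class 0:
        # accuracy 1/4; macro F1 = mean(2/5, 0, 0, 0) = 0.1
        q_true = np.repeat(np.arange(4), 5)
        q_pred = np.zeros(20, dtype=int)
        a = np.zeros(20, dtype=int)
        m = compute_metrics(a, a, q_true, q_pred, np.full(20, 10), n_areas=1)
        assert m.quadrant_accuracy == pytest.approx(0.25)
        assert m.quadrant_f1 == pytest.approx(0.1)

    def test_length_bins_cover_samples(self):
        a = np.arange(6) % 2
        q = np.zeros(6, dtype=int)
        lengths = np.array([5, 10, 15, 25, 45, 51])
        m = compute_metrics(a, a, q, q, lengths, n_areas=2)
        assert sorted(m.per_length_accuracy) == ["10", "20", "30", "50"]


class TestCrossValidation:
    def test_grouped_split_keeps_users_apart(self, rng):
        data = _toy_dataset(rng, n=40)
        cfg = ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                          fc_hidden=16, epochs=1, batch_size=8, seed=0)
        model = NextVisitModel(data, cfg)
        train_idx, test_idx = model._split(np.random.default_rng(0), group_by="user")
        assert sorted(train_idx + test_idx) == list(range(len(data)))
        train_users = {data[i].user_id for i in train_idx}
        test_users = {data[i].user_id for i in test_idx}
        assert not (train_users & test_users)

    def test_kfold_evaluate_averages(self, rng):
        data = _toy_dataset(rng, n=40)
        cfg = ModelConfig(n_areas=3, d_model=8, n_heads=2, lstm_hidden=8,
                          fc_hidden=16, epochs=3, batch_size=8, seed=0)
        m = evaluate(NextVisitModel(data, cfg), k_folds=3, epochs=3)
        assert 0.0 <= m.joint_accuracy <= 1.0
        assert m.n == 40
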