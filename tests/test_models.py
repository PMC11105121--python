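"""TSF features, architectures, and the training schedule."""

import dataclasses

import numpy as np
import pytest

from pedmet.cohorts import CohortDataset, WindowSpec
from pedmet.models import (
    ModelConfig,
    build_model,
    hyperparameter_search,
    predict_proba,
    random_intervals,
    train,
    tsf_interval_features,
)
from pedmet.nn import Tensor


def make_dataset(n=60, T=6, n_wide=3, seed=0, signal=1.0):
    """Directly constructed cohort with label signal in trajectory slope and wide means."""
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    traj = rng.normal(size=(n, T, 2))
    traj[:, :, 0] += signal * y[:, None] * np.linspace(0.0, 1.0, T)
    wide = rng.normal(size=(n, n_wide)) + 0.5 * signal * y[:, None]
    ws = WindowSpec("prediabetes", 4, 4 + T, (12.3, 18.0))
    return CohortDataset(traj, wide, y, [f"w{i}" for i in range(n_wide)], ws,
                         [f"P{i}" for i in range(n)])


ALL_KINDS = ["dw_tsf_cnn", "tsf_cnn", "recent_bmi_logistic", "random_forest", "crnn", "transformer"]


class TestTSFFeatures:
    def test_hand_computed_interval(self):
        out = tsf_interval_features(np.array([1.0, 2.0, 3.0, 4.0]), [(0, 3)])
        mean, sd, slope = out
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))  # population SD of [1,2,3]
        assert slope == pytest.approx(1.0)

    def test_constant_series(self):
        out = tsf_interval_features(np.full(5, 7.0), [(0, 5), (1, 3)])
        assert np.allclose(out, [7.0, 0.0, 0.0, 7.0, 0.0, 0.0])

    def test_single_point_interval(self):
        out = tsf_interval_features(np.array([1.0, 2.0, 3.0, 4.0]), [(2, 3)])
        assert np.allclose(out, [3.0, 0.0, 0.0])

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(IndexError):
            tsf_interval_features(np.arange(4.0), [(2, 6)])

    def test_batched_matches_single(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 8))
        intervals = [(0, 8), (2, 5), (7, 8)]
        batched = tsf_interval_features(X, intervals)
        for i in range(4):
            assert np.allclose(batched[i], tsf_interval_features(X[i], intervals))

    def test_random_intervals_reproducible_and_valid(self):
        a = random_intervals(10, 9, seed=5)
        assert a == random_intervals(10, 9, seed=5)
        assert all(0 <= s < e <= 10 for s, e in a)


class TestBuildModel:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_build_deterministic(self, kind):
        cfg = ModelConfig(kind=kind, seed=3)
        a = build_model(cfg, 6, 2, 3)
        b = build_model(cfg, 6, 2, 3)
        if kind == "random_forest":
            assert a.net.get_params() == b.net.get_params()
        else:
            for pa, pb in zip(a.net.parameters(), b.net.parameters()):
                assert np.array_equal(pa.data, pb.data)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="mlp")

    def test_wide_branch_is_linear_with_bias_at_zero(self):
        cfg = ModelConfig(kind="dw_tsf_cnn", seed=0)
        m = build_model(cfg, 6, 2, 4)
        out = m.net.wide(Tensor(np.zeros((2, 4))))
        assert np.allclose(out.data, m.net.wide.b.data)


class TestTraining:
    def test_single_class_rejected(self):
        ds = make_dataset(n=40)
        ds.labels[:] = 0
        cfg = ModelConfig(kind="recent_bmi_logistic", max_epochs=2)
        with pytest.raises(ValueError):
            train(build_model(cfg, 6, 2, 3), ds, cfg)

    @pytest.mark.parametrize("kind", ["dw_tsf_cnn", "random_forest"])
    def test_training_deterministic(self, kind):
        ds = make_dataset(n=40)
        cfg = ModelConfig(kind=kind, seed=7, max_epochs=5)
        m1 = train(build_model(cfg, 6, 2, 3), ds, cfg)
        m2 = train(build_model(cfg, 6, 2, 3), ds, cfg)
        p1 = predict_proba(m1, ds.trajectory_tensor, ds.wide_matrix)
        p2 = predict_proba(m2, ds.trajectory_tensor, ds.wide_matrix)
        assert np.array_equal(p1, p2)

    def test_lr_schedule_reproducible_from_loss_history(self):
        ds = make_dataset(n=40, signal=0.2)
        cfg = ModelConfig(kind="crnn", seed=1, max_epochs=25, val_frac=0.0)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        losses, lrs = m.history["train_loss"], m.history["lr"]
        lr, best, stall = cfg.learning_rate, np.inf, 0
        for i, loss in enumerate(losses):
            assert lrs[i] == pytest.approx(lr, rel=1e-12)
            if loss < best - 1e-9:
                best, stall = loss, 0
            else:
                stall += 1
                if stall >= cfg.lr_patience:
                    lr *= cfg.lr_decay
                    stall = 0

    def test_two_decay_events_give_0_92_squared(self):
        # frozen learning rate (0.0 updates) forces a stall every epoch:
        # decays fire at epochs 2, 5, 8, ... so 8 epochs contain exactly 2
        ds = make_dataset(n=40)
        cfg = ModelConfig(kind="recent_bmi_logistic", seed=0, max_epochs=8,
                          learning_rate=0.0, val_frac=0.0, early_stop_patience=50)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        # history records the rate in effect during each epoch
        assert m.history["lr"][-1] == pytest.approx(0.0)
        cfg2 = dataclasses.replace(cfg, learning_rate=0.001)
        lr = cfg2.learning_rate
        for _ in range(2):
            lr *= cfg2.lr_decay
        assert lr == pytest.approx(8.464e-4)

    def test_early_stop_after_fifteen_stalled_epochs(self):
        # zero learning rate: the monitored loss never improves after epoch 0,
        # so training stops at exactly 1 + 15 epochs
        ds = make_dataset(n=40)
        cfg = ModelConfig(kind="recent_bmi_logistic", seed=0, max_epochs=100,
                          learning_rate=0.0, val_frac=0.0)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        assert len(m.history["epoch"]) == 1 + cfg.early_stop_patience

    def test_improving_loss_runs_to_max_epochs(self):
        ds = make_dataset(n=60, signal=2.0)
        cfg = ModelConfig(kind="dw_tsf_cnn", seed=0, max_epochs=20, val_frac=0.0)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        assert len(m.history["epoch"]) <= 20


class TestPrediction:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_probabilities_valid_and_duplicate_rows_identical(self, kind):
        ds = make_dataset(n=40)
        cfg = ModelConfig(kind=kind, seed=2, max_epochs=3, n_estimators=20)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        dup_traj = np.repeat(ds.trajectory_tensor[:1], 3, axis=0)
        dup_wide = np.repeat(ds.wide_matrix[:1], 3, axis=0)
        p = predict_proba(m, dup_traj, dup_wide)
        assert np.all((p >= 0) & (p <= 1))
        assert p[0] == p[1] == p[2]

    def test_shape_mismatch_rejected(self):
        ds = make_dataset(n=40)
        cfg = ModelConfig(kind="dw_tsf_cnn", seed=0, max_epochs=2)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        with pytest.raises(ValueError):
            predict_proba(m, ds.trajectory_tensor[:, :4, :], ds.wide_matrix)

    def test_strong_signal_recovered(self):
        ds = make_dataset(n=200, signal=2.0, seed=5)
        cfg = ModelConfig(kind="dw_tsf_cnn", seed=0, max_epochs=40)
        m = train(build_model(cfg, 6, 2, 3), ds, cfg)
        held = make_dataset(n=100, signal=2.0, seed=6)
        from pedmet.evaluation import roc_auc

        assert roc_auc(predict_proba(m, held.trajectory_tensor, held.wide_matrix),
                       held.labels) > 0.8


class TestHyperparameterSearch:
    def test_budget_below_one_rejected(self):
        ds = make_dataset(n=60)
        with pytest.raises(ValueError):
            hyperparameter_search(ds, np.arange(40), ModelConfig(max_epochs=2), budget=0)

    def test_deterministic(self):
        ds = make_dataset(n=60)
        cfg = ModelConfig(kind="dw_tsf_cnn", max_epochs=2)
        a = hyperparameter_search(ds, np.arange(48), cfg, budget=2, seed=4)
        b = hyperparameter_search(ds, np.arange(48), cfg, budget=2, seed=4)
        assert a == b

    def test_never_touches_held_out_rows(self):
        ds = make_dataset(n=60)
        cfg = ModelConfig(kind="recent_bmi_logistic", max_epochs=2)
        train_ids = np.arange(48)
        test_ids = np.arange(48, 60)
        # corrupt the held-out rows: if the search read them, results would differ
        ds_corrupt = dataclasses.replace(
            ds,
            trajectory_tensor=ds.trajectory_tensor.copy(),
            wide_matrix=ds.wide_matrix.copy(),
        )
        ds_corrupt.trajectory_tensor[test_ids] = 1e6
        ds_corrupt.wide_matrix[test_ids] = -1e6
        a = hyperparameter_search(ds, train_ids, cfg, budget=2, seed=0)
        b = hyperparameter_search(ds_corrupt, train_ids, cfg, budget=2, seed=0)
        assert a == b
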