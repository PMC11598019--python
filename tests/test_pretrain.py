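"""Pre-training strategies: triplet loss and sampling, the λ schedule,
the grid harness, and the behaviour of the training loop itself."""

import numpy as np
import pytest

from semgnet.model import ModelConfig, build_mscnn
from semgnet.pretrain import (TrainConfig, TripletBatch, dann_lambda,
                              evaluate_windows, grid_search, sample_triplets,
                              train_backbone, triplet_margin_loss)
from tests.conftest import build_study


def small_model(pool, n_classes=4, seed=1):
    cfg = ModelConfig(window_len=pool.window_len, n_channels=12,
                      n_classes=n_classes, block1_channels=8,
                      post_concat_channels=32, sepconv_channels=32,
                      temporal_pool=7, seed=seed)
    return build_mscnn(cfg)


class TestTripletLoss:
    def test_hinge_boundary_inactive(self):
        # d(a,p)=0, d(a,n)=margin → exactly zero loss
        b = TripletBatch(anchor=np.array([[0.0, 0.0]]),
                         positive=np.array([[0.0, 0.0]]),
                         negative=np.array([[1.0, 0.0]]))
        assert triplet_margin_loss(b, margin=1.0).item() == pytest.approx(0.0, abs=1e-5)

    def test_hand_computed_example(self):
        # a=(0,0), p=(3,4), n=(0,1): max(0, 1 + 5 - 1) = 5
        b = TripletBatch(anchor=np.array([[0.0, 0.0]]),
                         positive=np.array([[3.0, 4.0]]),
                         negative=np.array([[0.0, 1.0]]))
        assert triplet_margin_loss(b, margin=1.0).item() == pytest.approx(5.0)

    def test_batch_decomposes_into_singles(self):
        rng = np.random.default_rng(0)
        a, p, n = (rng.standard_normal((6, 4)) for _ in range(3))
        whole = triplet_margin_loss(TripletBatch(a, p, n), 0.7).item()
        singles = sum(
            triplet_margin_loss(TripletBatch(a[i:i+1], p[i:i+1], n[i:i+1]),
                                0.7).item()
            for i in range(6))
        assert whole == pytest.approx(singles, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_margin_loss(TripletBatch(np.zeros((2, 3)),
                                             np.zeros((2, 3)),
                                             np.zeros((2, 4))), 1.0)


class TestSampleTriplets:
    def _pool(self):
        subjects = np.array(["A", "A", "B", "B", "A", "B"])
        labels = np.array([0, 1, 0, 1, 0, 1])
        emb = np.arange(12, dtype=float).reshape(6, 2)
        return subjects, labels, emb

    def test_all_triplets_satisfy_invariants(self):
        subjects, labels, emb = self._pool()
        tb = sample_triplets(subjects, emb, np.random.default_rng(0),
                             labels=labels)
        for (sa, sp, sn), (la, lp, ln) in zip(tb.subjects, tb.labels):
            assert sp != sa and lp == la      # positive: other subject, same label
            assert ln != la                   # negative: other label

    def test_single_subject_pool_is_error(self):
        with pytest.raises(ValueError, match="two subjects"):
            sample_triplets(np.array(["A", "A"]), np.zeros((2, 2)),
                            np.random.default_rng(0), labels=np.array([0, 1]))

    def test_seeded_rng_reproducible(self):
        subjects, labels, emb = self._pool()
        a = sample_triplets(subjects, emb, np.random.default_rng(5), labels=labels)
        b = sample_triplets(subjects, emb, np.random.default_rng(5), labels=labels)
        assert np.array_equal(a.indices, b.indices)


class TestDannLambda:
    def test_starts_at_zero(self):
        assert dann_lambda(0.0, 10.0) == pytest.approx(0.0)

    def test_monotone_nondecreasing_on_grid(self):
        vals = [dann_lambda(p, 10.0) for p in np.linspace(0, 1, 100)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_approaches_one_from_below(self):
        assert 0.999 < dann_lambda(1.0, 10.0) < 1.0
        assert dann_lambda(1.0, 50.0) == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dann_lambda(1.5, 10.0)
        with pytest.raises(ValueError):
            dann_lambda(0.5, -1.0)


class TestGridSearch:
    def test_exhaustive_2x2_ranking(self):
        space = {"lr": [0.1, 0.2], "bs": [8, 16]}
        scores = {(0.1, 8): 0.5, (0.1, 16): 0.9, (0.2, 8): 0.1, (0.2, 16): 0.7}
        ranked = grid_search(space, lambda c: scores[(c["lr"], c["bs"])])
        assert len(ranked) == 4
        assert [m for _, m in ranked] == sorted(scores.values(), reverse=True)
        assert ranked[0][0] == {"lr": 0.1, "bs": 16}

    def test_budget_one(self):
        ranked = grid_search({"a": [1, 2, 3]}, lambda c: c["a"], budget=1)
        assert len(ranked) == 1

    def test_table3_axes_accepted_as_keys(self):
        space = {"Batch size": [64, 256], "Optimizer": ["Adam"],
                 "Learning rate": [1e-3], "Decay rate": [0],
                 "Activation function": ["LeakyReLU"],
                 "Pooling type": ["MaxPooling"],
                 "N_Multi-kernel": [64], "N_Post-Concatenation": [128],
                 "N_Separable_Conv": [256]}
        ranked = grid_search(space, lambda c: float(c["Batch size"]))
        assert ranked[0][0]["Batch size"] == 256

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            grid_search({}, lambda c: 0.0)


class TestTrainBackbone:
    def test_zero_epochs_leaves_weights_untouched(self):
        sets, _, _, split, pool = build_study(seed=4, n_subjects=4,
                                              n_amputees=0,
                                              n_hold_healthy=0,
                                              n_hold_amputee=0)
        model = small_model(pool)
        before = [p.data.copy() for p in model.parameters()]
        cfg = TrainConfig(strategy="standard", max_epochs=0, patience=0, seed=0)
        model, hist = train_backbone(model, split, pool, cfg)
        for b, p in zip(before, model.parameters()):
            assert np.array_equal(b, p.data)
        assert hist.best_epoch == -1

    def test_dann_with_lambda_zero_matches_standard_trajectory(self):
        """With λ pinned at 0 the reversal branch contributes nothing and
        the backbone follows the plain classification path step for step."""
        sets, _, _, split, pool = build_study(seed=4, n_subjects=4,
                                              n_amputees=0,
                                              n_hold_healthy=0,
                                              n_hold_amputee=0)
        # one epoch of many batches: training progress stays 0, so the
        # schedule pins λ to exactly 0 for every step
        cfg_kw = dict(batch_size=64, learning_rate=1e-3, max_epochs=1,
                      patience=1, seed=3)
        m_std = small_model(pool, seed=3)
        m_std, h_std = train_backbone(m_std, split, pool,
                                      TrainConfig(strategy="standard", **cfg_kw))
        m_dann = small_model(pool, seed=3)
        m_dann.add_domain_head(4)
        m_dann, hist = train_backbone(
            m_dann, split, pool, TrainConfig(strategy="dann", **cfg_kw))
        assert hist.lambdas == [0.0]
        assert hist.val_loss[0] == pytest.approx(h_std.val_loss[0], abs=1e-6)
        for a, b in zip(m_std.parameters(parts=[1, 2, 3, 4]),
                        m_dann.parameters(parts=[1, 2, 3, 4])):
            assert np.allclose(a.data, b.data, atol=1e-7)

    def test_standard_learns_small_cohort(self):
        """Scaled learnability check: 6 subjects, 4 classes, intra split."""
        sets, _, _, split, pool = build_study(seed=2, n_subjects=6,
                                              n_amputees=1,
                                              n_hold_healthy=0,
                                              n_hold_amputee=0)
        model = small_model(pool, seed=2)
        cfg = TrainConfig(strategy="standard", batch_size=128,
                          learning_rate=2e-3, max_epochs=30, patience=6, seed=2)
        model, hist = train_backbone(model, split, pool, cfg)
        assert max(hist.val_acc) > 0.8

    def test_triplet_training_contracts_same_class_other_subject(self):
        """After metric pre-training, cross-subject same-gesture pairs are
        closer in embedding space than different-gesture pairs."""
        from semgnet.pretrain import _eval_features
        from semgnet.protocol import assign_windows
        sets, _, _, split, pool = build_study(seed=6, n_subjects=4,
                                              n_amputees=0,
                                              n_hold_healthy=0,
                                              n_hold_amputee=0)
        model = small_model(pool, seed=6)
        cfg = TrainConfig(strategy="triplet", batch_size=128,
                          learning_rate=2e-3, max_epochs=6, patience=6,
                          margin=1.0, seed=6)
        model, hist = train_backbone(model, split, pool, cfg)
        tr, _, _ = assign_windows(pool, split)
        sub = tr[::4]
        emb = _eval_features(model, pool.windows[sub].astype(np.float32))
        labels = pool.labels[sub]
        subjects = pool.subject_ids[sub]
        d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        same = (labels[:, None] == labels[None, :]) & \
               (subjects[:, None] != subjects[None, :])
        diff = labels[:, None] != labels[None, :]
        assert d[same].mean() < d[diff].mean()

    def test_dann_history_records_components_and_ramp(self):
        sets, _, _, split, pool = build_study(seed=4, n_subjects=4,
                                              n_amputees=0,
                                              n_hold_healthy=0,
                                              n_hold_amputee=0)
        model = small_model(pool, seed=4)
        cfg = TrainConfig(strategy="dann", batch_size=128, learning_rate=1e-3,
                          max_epochs=3, patience=3, seed=4)
        model, hist = train_backbone(model, split, pool, cfg)
        assert len(hist.class_loss) == len(hist.domain_loss) == 3
        # λ ramps monotonically from 0: ever more weight against domain accuracy
        assert hist.lambdas[0] == pytest.approx(0.0)
        assert all(b >= a for a, b in zip(hist.lambdas, hist.lambdas[1:]))
        assert hist.lambdas[-1] > 0.9

    def test_strategy_requirements_validated(self):
        sets, _, _, split, pool = build_study(seed=4, n_subjects=4,
                                              n_amputees=0,
                                              n_hold_healthy=0,
                                              n_hold_amputee=0)
        with pytest.raises(ValueError, match="strategy"):
            TrainConfig(strategy="contrastive").validate()
        with pytest.raises(ValueError, match="batch_size"):
            TrainConfig(strategy="triplet", batch_size=1).validate()
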