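import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgbp.model import (
    BPSystem,
    ExtractorConfig,
    PreparedDataset,
    TrainConfig,
    TrainedExtractor,
    ablate_inputs,
    attention_score,
    attention_weights,
    build_extractor,
    fuse,
    mse_loss,
    train_attention,
    train_full_system,
    train_single_channel,
)


class TestExtractorStructure:
    def test_latent_and_head_shapes(self):
        ext = build_extractor(seed=0)
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=(2, 3, 1720)).astype(np.float32)
        x2 = rng.normal(size=(2, 3, 1720)).astype(np.float32)
        x3 = rng.normal(size=(2, 1, 215)).astype(np.float32)
        z = ext.features(x1, x2, x3)
        assert z.shape == (2, 16)
        assert np.all((z > 0) & (z < 1))
        y = ext.forward(x1, x2, x3)
        assert y.shape == (2,)

    def test_layer_trace_matches_published_chain(self):
        """Per-stream lengths follow the printed architecture table:
        PPG 1720-860-860-860-430-215-108, force 215-108-108-108-54-27-14."""
        ext = build_extractor(seed=0)
        rng = np.random.default_rng(0)
        trace = ext.shape_trace(
            rng.normal(size=(1, 3, 1720)).astype(np.float32),
            rng.normal(size=(1, 3, 1720)).astype(np.float32),
            rng.normal(size=(1, 1, 215)).astype(np.float32),
        )
        ppg_expected = [
            (4, 860), (4, 860), (4, 860), (4, 860),
            (8, 430), (16, 215), (32, 108), (32,),
        ]
        force_expected = [
            (4, 108), (4, 108), (4, 108), (4, 108),
            (8, 54), (16, 27), (32, 14), (32,),
        ]
        assert [s[1:] for s in trace["x1"]] == ppg_expected
        assert [s[1:] for s in trace["x2"]] == ppg_expected
        assert [s[1:] for s in trace["x3"]] == force_expected

    def test_concatenated_pooled_width_is_96(self):
        cfg = ExtractorConfig()
        assert 3 * cfg.block_widths[-1] == 96
        ext = build_extractor(cfg, seed=0)
        assert ext.fc.w.value.shape == (16, 96)

    def test_wrong_input_lengths_rejected(self):
        ext = build_extractor(seed=0)
        bad = np.zeros((1, 3, 1000), dtype=np.float32)
        ok = np.zeros((1, 3, 1720), dtype=np.float32)
        with pytest.raises(ValueError):
            ext.features(bad, ok, np.zeros((1, 1, 215), dtype=np.float32))
        with pytest.raises(ValueError):
            ext.features(ok, ok, np.zeros((1, 1, 200), dtype=np.float32))

    def test_seeded_builds_identical(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=(2, 3, 1720)).astype(np.float32)
        x3 = rng.normal(size=(2, 1, 215)).astype(np.float32)
        a = build_extractor(seed=3).forward(x1, x1, x3)
        b = build_extractor(seed=3).forward(x1, x1, x3)
        assert np.array_equal(a, b)


class TestMSELoss:
    def test_hand_examples(self):
        assert mse_loss([120.0, 80.0], [120.0, 80.0]) == 0.0
        assert mse_loss([120.0], [118.0]) == 4.0
        assert mse_loss([120.0, 80.0, 100.0], [122.0, 79.0, 97.0]) == pytest.approx(14 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([1.0, 2.0], [1.0])


class TestAttentionPrimitives:
    def test_zero_weights_give_zero_scores(self):
        Z = np.random.default_rng(0).random((16, 9))
        assert np.array_equal(attention_score(Z, np.zeros(16), 0.0), np.zeros(9))

    def test_identical_columns_equal_scores(self):
        col = np.random.default_rng(1).random(16)
        Z = np.tile(col[:, None], (1, 9))
        s = attention_score(Z, np.random.default_rng(2).normal(size=16), 0.3)
        assert np.allclose(s, s[0])

    def test_basis_vector_score_reads_first_row(self):
        Z = np.random.default_rng(3).random((16, 9))
        omega = np.zeros(16)
        omega[0] = 1.0
        assert attention_score(Z, omega, 1.0) == pytest.approx(Z[0] + 1.0)

    def test_uniform_scores_uniform_weights(self):
        assert attention_weights(np.full(9, 2.5)) == pytest.approx(np.full(9, 1 / 9))

    def test_dominant_score_takes_almost_all_weight(self):
        s = np.zeros(9)
        s[0] = 10.0
        assert attention_weights(s)[0] > 0.999

    def test_shift_invariance(self):
        s = np.random.default_rng(4).normal(size=9)
        assert attention_weights(s) == pytest.approx(attention_weights(s + 5.0), abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=9, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_softmax_simplex_property(self, scores):
        w = attention_weights(np.array(scores))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_one_hot_fusion_selects_column(self):
        Z = np.random.default_rng(5).random((16, 9))
        w = np.zeros(9)
        w[2] = 1.0
        assert np.array_equal(fuse(Z, w), Z[:, 2])

    def test_uniform_fusion_is_column_mean(self):
        Z = np.random.default_rng(6).random((16, 9))
        assert fuse(Z, np.full(9, 1 / 9)) == pytest.approx(Z.mean(axis=1))

    def test_two_channel_average(self):
        Z = np.random.default_rng(7).random((16, 9))
        w = np.zeros(9)
        w[0] = w[1] = 0.5
        assert fuse(Z, w) == pytest.approx((Z[:, 0] + Z[:, 1]) / 2)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((16, 8)), np.zeros(9))
        with pytest.raises(ValueError):
            attention_score(np.zeros((15, 9)), np.zeros(15), 0.0)


class TestAblation:
    def test_identity_mode(self, tiny_dataset):
        case0 = _first_case(tiny_dataset)
        out = ablate_inputs(case0, "P+E+F")
        assert np.array_equal(out.x1, case0.x1)
        assert np.array_equal(out.x2, case0.x2)

    def test_stream_masking(self, tiny_dataset):
        case0 = _first_case(tiny_dataset)
        pf = ablate_inputs(case0, "P+F")
        assert np.all(pf.x2 == 0) and np.array_equal(pf.x1, case0.x1)
        ef = ablate_inputs(case0, "E+F")
        assert np.all(ef.x1 == 0) and np.array_equal(ef.x2, case0.x2)

    def test_unknown_mode_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            ablate_inputs(_first_case(tiny_dataset), "P")


def _first_case(dataset: PreparedDataset):
    from ppgbp.preprocess import PreparedCase

    return PreparedCase(
        case_id=dataset.case_ids[0],
        subject_id=str(dataset.subject_ids[0]),
        x1=dataset.x1[0],
        x2=dataset.x2[0],
        x3=dataset.x3[0],
        ref_sbp=float(dataset.sbp[0]),
        ref_dbp=float(dataset.dbp[0]),
    )


@pytest.fixture(scope="module")
def tiny_split(tiny_dataset):
    subs = np.unique(tiny_dataset.subject_ids)
    tr = np.where(np.isin(tiny_dataset.subject_ids, subs[:6]))[0]
    va = np.where(np.isin(tiny_dataset.subject_ids, subs[6:]))[0]
    return tiny_dataset.subset(tr), tiny_dataset.subset(va)


class TestStage1Training:
    def test_loss_decreases_on_learnable_data(self, tiny_split):
        train, _ = tiny_split
        cfg = TrainConfig(target="DBP", epochs=4, patience=4, seed=1)
        trained = train_single_channel(train, 5, cfg)
        losses = [h["train_mse_std"] for h in trained.history]
        assert losses[-1] < losses[0]

    def test_seeded_training_reproducible(self, tiny_split):
        train, val = tiny_split
        cfg = TrainConfig(target="DBP", epochs=2, patience=2, seed=3)
        a = train_single_channel(train, 2, cfg, val)
        b = train_single_channel(train, 2, cfg, val)
        pa = a.predict(*val.channel(1))
        pb = b.predict(*val.channel(1))
        assert np.array_equal(pa, pb)

    def test_shuffled_labels_no_better_than_mean(self, tiny_split):
        """With labels randomly permuted across cases, held-out MSE stays in
        the vicinity of the label variance (the mean predictor's MSE)."""
        train, val = tiny_split
        shuffled = train.subset(np.arange(len(train)))
        rng = np.random.default_rng(0)
        shuffled.dbp = rng.permutation(shuffled.dbp)
        cfg = TrainConfig(target="DBP", epochs=4, patience=4, seed=1)
        trained = train_single_channel(shuffled, 5, cfg)
        pred = trained.predict(*val.channel(4))
        mse = mse_loss(val.dbp, pred)
        var = float(val.dbp.var()) + (val.dbp.mean() - shuffled.dbp.mean()) ** 2
        assert mse > 0.5 * var

    def test_invalid_channel_and_stage(self, tiny_split):
        train, _ = tiny_split
        with pytest.raises(ValueError):
            train_single_channel(train, 0, TrainConfig(target="DBP", epochs=1, seed=0))
        with pytest.raises(ValueError):
            train_single_channel(
                train, 1, TrainConfig(target="DBP", stage="attention", epochs=1, seed=0)
            )


class TestAttentionTraining:
    def test_informative_channel_upweighted_on_constructed_latents(self):
        """Latent banks where only channel 3 encodes the label: after stage-2
        training its mean attention weight is the largest."""
        rng = np.random.default_rng(0)
        n = 400
        y = rng.uniform(60, 105, n)
        # uninformative channels carry per-case noise, so averaging them into
        # the fused feature costs accuracy and attention must concentrate
        feats = np.clip(0.5 + 0.15 * rng.normal(size=(n, 9, 16)), 0.01, 0.99)
        yn = (y - y.mean()) / y.std()
        signal_dirs = rng.normal(size=16)
        feats[:, 2, :] = 1 / (1 + np.exp(-(yn[:, None] * signal_dirs)))
        cfg = TrainConfig(target="DBP", stage="attention", epochs=200,
                          patience=200, seed=0)
        head, _ = train_attention(feats, y, cfg, (float(y.mean()), float(y.std())))
        _, w = head.forward(feats)
        mean_w = w.mean(axis=0)
        assert np.argmax(mean_w) == 2
        assert mean_w[2] > 2 / 9

    def test_weights_sum_to_one_untrained(self):
        rng = np.random.default_rng(1)
        feats = rng.random((20, 9, 16))
        y = rng.uniform(60, 105, 20)
        cfg = TrainConfig(target="DBP", stage="attention", epochs=1, seed=0)
        head, _ = train_attention(feats, y, cfg, (80.0, 10.0))
        _, w = head.forward(feats)
        assert w.sum(axis=1) == pytest.approx(np.ones(20), abs=1e-6)


@pytest.fixture(scope="module")
def tiny_system(tiny_split):
    """Full two-stage system at minimal scale (structure/inference tests)."""
    train, val = tiny_split
    cfg = TrainConfig(target="DBP", epochs=2, patience=2, seed=2)
    return train_full_system(train, cfg, val)


class TestFullSystem:
    def test_predict_attaches_simplex_weights(self, tiny_system, tiny_dataset):
        est = tiny_system.predict(_first_case(tiny_dataset))
        assert est.target == "DBP"
        assert np.isfinite(est.value)
        assert est.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_inference_deterministic(self, tiny_system, tiny_dataset):
        case = _first_case(tiny_dataset)
        assert tiny_system.predict(case).value == tiny_system.predict(case).value

    def test_topk_keeps_k_channels(self, tiny_system, tiny_dataset):
        case = _first_case(tiny_dataset)
        for k in (2, 3):
            est = tiny_system.predict_topk(case, k)
            nonzero = np.count_nonzero(est.weights)
            assert nonzero == k
            assert est.weights.sum() == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            tiny_system.predict_topk(case, 4)

    def test_channel_ranking_available(self, tiny_system):
        assert sorted(tiny_system.channel_ranking) == list(range(1, 10))

    def test_mixed_target_extractors_rejected(self, tiny_system):
        bad = list(tiny_system.extractors)
        import dataclasses

        bad[0] = dataclasses.replace(bad[0], target="SBP")
        with pytest.raises(ValueError):
            BPSystem(
                target="DBP",
                extractors=bad,
                attention=tiny_system.attention,
                y_mean=tiny_system.y_mean,
                y_std=tiny_system.y_std,
            )
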