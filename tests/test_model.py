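"""CNN towers, predictor, and the supervised training loop."""

import numpy as np
import pytest

from fragdta import (
    AffinityRecord,
    CNNConfig,
    EncoderConfig,
    GINEncoder,
    PredictorConfig,
    TrainOptions,
    build_bundle,
    cnn_high_level,
    concat_pair,
    load_bundle,
    predict_affinity,
    predict_pairs,
    save_bundle,
    train_supervised,
)
from fragdta.autograd import Tensor
from fragdta.features import LowLevelDrugFeatures, LowLevelTargetFeatures
from fragdta.model import CNN2D, Predictor


SMALL_CNN = CNNConfig(n_layers=2, filters=(4, 6), kernels=(3, 3),
                      pooling=("max2", "global"))


class TestCNN:
    def test_output_dimension_is_last_filter_count(self, rng):
        cnn = CNN2D(CNNConfig(), 64, 60, rng)
        out = cnn(Tensor(rng.normal(size=(2, 1, 64, 60)).astype(np.float32)))
        assert out.shape == (2, 128)

    def test_zero_input_bias_free_gives_zero_output(self, rng):
        cnn = CNN2D(SMALL_CNN, 16, 10, rng)
        for b in cnn.biases:
            b.data[:] = 0.0
        out = cnn(Tensor(np.zeros((3, 1, 16, 10), dtype=np.float32)))
        assert np.all(out.data == 0.0)

    def test_deterministic_across_calls(self, rng):
        cnn = CNN2D(SMALL_CNN, 16, 10, rng)
        x = Tensor(rng.normal(size=(2, 1, 16, 10)).astype(np.float32))
        assert np.array_equal(cnn(x).data, cnn(x).data)

    def test_shape_mismatch_raises_with_expected_and_got(self, rng):
        cnn = CNN2D(SMALL_CNN, 16, 10, rng)
        with pytest.raises(ValueError, match=r"expected \(B, 1, 16, 10\)"):
            cnn(Tensor(np.zeros((1, 1, 8, 10), dtype=np.float32)))

    def test_1d_variant_runs_and_pools_rows_only(self, rng):
        cfg = CNNConfig(n_layers=2, filters=(4, 6), kernels=(3, 3),
                        pooling=("max2", "global"), use_1d=True)
        cnn = CNN2D(cfg, 16, 10, rng)
        out = cnn(Tensor(rng.normal(size=(2, 1, 16, 10)).astype(np.float32)))
        assert out.shape == (2, 6)

    def test_parameter_count_matches_hand_formula(self, rng):
        # conv params: f * (c_in * k * k) + f per layer
        cnn = CNN2D(CNNConfig(), 64, 60, rng)
        expected = (32 * (1 * 5 * 5) + 32) + (64 * (32 * 5 * 5) + 64) \
            + (128 * (64 * 3 * 3) + 128)
        assert cnn.n_params() == expected


class TestPredictor:
    def test_default_sizes(self, rng):
        p = Predictor(256, PredictorConfig(), rng)
        expected = (256 * 512 + 512) + (512 * 128 + 128) + (128 * 1 + 1)
        assert p.n_params() == expected

    def test_hand_computed_toy(self, rng):
        # 2 -> 2 -> 1 with hand-set weights:
        # h = relu(x @ W1 + b1), y = h @ W2 + b2
        p = Predictor(2, PredictorConfig(hidden_sizes=(2, 1)), rng)
        l1, l2 = p.mlp.layers
        l1.W.data = np.array([[1.0, -1.0], [0.5, 2.0]], dtype=np.float32)
        l1.b.data = np.array([0.0, 1.0], dtype=np.float32)
        l2.W.data = np.array([[2.0], [-1.0]], dtype=np.float32)
        l2.b.data = np.array([0.5], dtype=np.float32)
        x = np.array([1.0, 2.0])
        h = np.maximum(x @ l1.W.data + l1.b.data, 0.0)   # [2, 4]
        expected = float((h @ l2.W.data + l2.b.data)[0])  # 2*2 - 4 + 0.5 = 0.5
        assert predict_affinity(x, p) == pytest.approx(expected, abs=1e-6)
        assert predict_affinity(x, p) == predict_affinity(x, p)

    def test_zero_weights_zero_input_gives_zero(self, rng):
        p = Predictor(4, PredictorConfig(hidden_sizes=(3, 1)), rng)
        for t in p.params():
            t.data[:] = 0.0
        assert predict_affinity(np.zeros(4), p) == 0.0

    def test_length_mismatch_raises(self, rng):
        p = Predictor(4, PredictorConfig(hidden_sizes=(3, 1)), rng)
        with pytest.raises(ValueError, match="expected 4"):
            predict_affinity(np.zeros(5), p)


class TestConcatPair:
    def test_length_and_order(self):
        a, b = np.ones(3), np.full(2, 2.0)
        out = concat_pair(a, b)
        assert out.shape == (5,)
        assert np.array_equal(out, [1, 1, 1, 2, 2])
        assert not np.array_equal(concat_pair(a[:2], b), concat_pair(b, a[:2]))

    def test_zero_drug_vector_zeroes_first_half(self):
        out = concat_pair(np.zeros(4), np.ones(4))
        assert np.all(out[:4] == 0) and np.all(out[4:] == 1)

    def test_missing_component_raises(self):
        with pytest.raises(ValueError):
            concat_pair(None, np.ones(2))


def _toy_training_setup(seed=0, n_drugs=6, n_targets=4, d=6, rows=8, k=8):
    """A miniature but complete supervised problem with planted structure."""
    rng = np.random.default_rng(seed)
    drug_feats, target_feats, records = {}, {}, []
    drug_sig = rng.normal(size=(n_drugs,))
    target_sig = rng.normal(size=(n_targets,))
    for i in range(n_drugs):
        m = rng.normal(size=(rows, d)).astype(np.float32)
        m[0, 0] = drug_sig[i]
        drug_feats[f"D{i}"] = LowLevelDrugFeatures(m, f"D{i}", rows)
    for j in range(n_targets):
        m = rng.normal(size=(k, d)).astype(np.float32)
        m[0, 0] = target_sig[j]
        target_feats[f"T{j}"] = LowLevelTargetFeatures(
            m, f"T{j}", np.zeros(k, dtype=bool))
    for i in range(n_drugs):
        for j in range(n_targets):
            y = 2.0 * drug_sig[i] + target_sig[j] + 0.05 * rng.normal()
            records.append(AffinityRecord(f"D{i}", f"T{j}", float(y)))
    denc = GINEncoder(EncoderConfig(n_layers=1, hidden_size=d), 62, rng)
    tenc = GINEncoder(EncoderConfig(n_layers=1, hidden_size=d), 25, rng)
    bundle = build_bundle(
        denc, tenc, drug_rows=rows, k=k,
        drug_cnn_config=SMALL_CNN, target_cnn_config=SMALL_CNN,
        predictor_config=PredictorConfig(hidden_sizes=(16, 1)), seed=seed,
    )
    return records, bundle, drug_feats, target_feats


class TestTrainSupervised:
    def test_loss_decreases(self):
        records, bundle, df, tf = _toy_training_setup()
        res = train_supervised(records, bundle, df, tf,
                               TrainOptions(epochs=15, batch_size=8, seed=0))
        h = res.history
        assert h.train_mse.iloc[-1] < h.train_mse.iloc[0]
        assert list(h.columns) == ["epoch", "train_mse", "val_mse", "val_ci"]

    def test_seeded_runs_are_identical(self):
        outs = []
        for _ in range(2):
            records, bundle, df, tf = _toy_training_setup(seed=3)
            res = train_supervised(records, bundle, df, tf,
                                   TrainOptions(epochs=4, batch_size=8, seed=3))
            outs.append((res.history, predict_pairs(bundle, records, df, tf)))
        assert outs[0][0].equals(outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_too_few_records_rejected(self):
        records, bundle, df, tf = _toy_training_setup()
        with pytest.raises(ValueError):
            train_supervised(records[:1], bundle, df, tf, TrainOptions())

    def test_unresolvable_id_rejected(self):
        records, bundle, df, tf = _toy_training_setup()
        records.append(AffinityRecord("D999", "T0", 1.0))
        with pytest.raises(KeyError, match="D999"):
            train_supervised(records, bundle, df, tf, TrainOptions())

    def test_bundle_checkpoint_roundtrip(self, tmp_path):
        records, bundle, df, tf = _toy_training_setup(seed=5)
        train_supervised(records, bundle, df, tf,
                         TrainOptions(epochs=2, batch_size=8, seed=5))
        before = predict_pairs(bundle, records[:5], df, tf)
        save_bundle(bundle, tmp_path / "model.ckpt")
        loaded = load_bundle(tmp_path / "model.ckpt")
        after = predict_pairs(loaded, records[:5], df, tf)
        assert np.array_equal(before, after)


class TestCnnHighLevel:
    def test_accepts_feature_objects_and_arrays(self, rng):
        cnn = CNN2D(SMALL_CNN, 8, 6, rng)
        mat = rng.normal(size=(8, 6)).astype(np.float32)
        feats = LowLevelDrugFeatures(mat, "D0", 8)
        assert np.array_equal(cnn_high_level(feats, cnn), cnn_high_level(mat, cnn))
        assert cnn_high_level(feats, cnn).shape == (6,)


def test_cnn_config_validation():
    with pytest.raises(ValueError):
        CNNConfig(n_layers=2, filters=(4,), kernels=(3, 3), pooling=("max2", "global"))
    with pytest.raises(ValueError):
        CNNConfig(n_layers=1, filters=(4,), kernels=(3,), pooling=("max2",))


def test_affinity_record_requires_finite_label():
    with pytest.raises(ValueError):
        AffinityRecord("D0", "T0", float("nan"))
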