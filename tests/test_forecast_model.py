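import numpy as np
import pytest

from forestcast.errors import IncompatibleCheckpointError
from forestcast.forecast_model import (
    ConditionCode,
    ForecastConfig,
    NextFrameForecaster,
    SeriesSample,
    condition_width,
    encode_condition,
    load_model,
    predict_next,
    save_model,
    train,
)

FS = 16  # small frames keep unit tests fast


def tiny_config(**kw):
    defaults = dict(
        j=3,
        frame_size=FS,
        feature_dim=32,
        latent_dim=16,
        recurrent_hidden=32,
        condition_width=4,
        itr=5,
        learning_rate=1e-3,
        batch_size=4,
        seed=0,
    )
    defaults.update(kw)
    return ForecastConfig(**defaults)


def make_sample(rng, ordinal=0, width=4, target=None):
    inputs = [rng.random((FS, FS)) for _ in range(3)]
    if target is None:
        target = rng.random((FS, FS))
    return SeriesSample(condition=encode_condition(ordinal, width), inputs=inputs, target=target)


class TestConditionCode:
    def test_seventh_block_encodes_as_0111(self):
        assert str(encode_condition(7, 4)) == "0111"

    def test_zero_pads_to_width(self):
        assert str(encode_condition(0, 4)) == "0000"

    def test_binary_expansion(self):
        assert str(encode_condition(10, 4)) == "1010"

    def test_bijective_over_width_range(self):
        seen = set()
        for k in range(16):
            code = encode_condition(k, 4)
            assert code.ordinal == k
            seen.add(code.bits)
        assert len(seen) == 16

    def test_overflow_rejected(self):
        with pytest.raises(OverflowError):
            encode_condition(16, 4)

    def test_width_for_block_counts(self):
        assert condition_width(2) == 1
        assert condition_width(255) == 8
        assert condition_width(256) == 8
        assert condition_width(257) == 9


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    samples = [make_sample(rng, ordinal=i % 4) for i in range(4)]
    return train(samples, tiny_config(itr=2))


class TestForwardContracts:

    def test_feature_vectors_have_feature_dim(self, fitted, rng):
        frames = [rng.random((FS, FS)) for _ in range(3)]
        feats = fitted.extract_features(frames)
        assert len(feats) == 3 and all(v.shape == (32,) for v in feats)

    def test_identical_frames_give_identical_features(self, fitted, rng):
        f = rng.random((FS, FS))
        feats = fitted.extract_features([f, f, f])
        np.testing.assert_array_equal(feats[0], feats[1])
        np.testing.assert_array_equal(feats[1], feats[2])

    def test_inference_latent_is_deterministic(self, fitted, rng):
        feats = fitted.extract_features([rng.random((FS, FS)) for _ in range(3)])
        z1 = fitted.encode_sequence(feats)
        z2 = fitted.encode_sequence(feats)
        assert z1.shape == (16,)
        np.testing.assert_array_equal(z1, z2)

    def test_seeded_sampling_is_reproducible(self, fitted, rng):
        feats = fitted.extract_features([rng.random((FS, FS)) for _ in range(3)])
        z1 = fitted.encode_sequence(feats, rng=np.random.default_rng(7))
        z2 = fitted.encode_sequence(feats, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(z1, z2)

    def test_generated_frame_shape_and_range(self, fitted, rng):
        z = rng.normal(size=16)
        frame = fitted.generate_frame(z, encode_condition(2, 4))
        assert frame.shape == (FS, FS)
        assert frame.min() >= 0.0 and frame.max() <= 1.0

    def test_prediction_bit_identical_across_calls(self, fitted, rng):
        frames = [rng.random((FS, FS)) for _ in range(3)]
        cond = encode_condition(1, 4)
        np.testing.assert_array_equal(
            fitted.predict_next(frames, cond), fitted.predict_next(frames, cond)
        )

    def test_wrong_frame_count_rejected(self, fitted, rng):
        with pytest.raises(ValueError, match="frames"):
            fitted.predict_next([rng.random((FS, FS))] * 2, encode_condition(0, 4))


class TestTraining:
    def test_overfit_single_constant_sample(self):
        rng = np.random.default_rng(3)
        target = np.full((FS, FS), 0.5)
        sample = SeriesSample(
            condition=encode_condition(0, 4),
            inputs=[rng.random((FS, FS)) for _ in range(3)],
            target=target,
        )
        res = train([sample], tiny_config(itr=200, learning_rate=3e-3, batch_size=1))
        assert res.training_log[-1] < res.training_log[0]
        pred = res.predict_next(sample.inputs, sample.condition)
        assert np.abs(pred - 0.5).max() < 0.05

    def test_training_log_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        samples = [make_sample(rng, ordinal=i) for i in range(4)]
        log1 = train(samples, tiny_config(itr=5)).training_log
        log2 = train(samples, tiny_config(itr=5)).training_log
        assert log1 == log2

    def test_kl_weight_zero_is_pure_reconstruction(self):
        # with kl_weight 0 the loss is just MSE: check it against the
        # prediction error of an untrained single step
        rng = np.random.default_rng(8)
        samples = [make_sample(rng)]
        cfg = tiny_config(itr=1, batch_size=1, kl_weight=0.0)
        res = train(samples, cfg)
        assert len(res.training_log) == 1
        assert np.isfinite(res.training_log[0])

    def test_kl_weight_increases_loss(self):
        rng = np.random.default_rng(8)
        samples = [make_sample(rng)]
        l0 = train(samples, tiny_config(itr=1, batch_size=1, kl_weight=0.0)).training_log[0]
        l1 = train(samples, tiny_config(itr=1, batch_size=1, kl_weight=1.0)).training_log[0]
        assert l1 > l0

    def test_condition_disambiguates_blocks(self):
        # two blocks with very different constant targets, same inputs:
        # only the condition code can tell them apart
        rng = np.random.default_rng(11)
        inputs = [rng.random((FS, FS)) for _ in range(3)]
        s0 = SeriesSample(encode_condition(0, 4), inputs, np.full((FS, FS), 0.1))
        s1 = SeriesSample(encode_condition(1, 4), inputs, np.full((FS, FS), 0.9))
        res = train([s0, s1], tiny_config(itr=300, learning_rate=3e-3, batch_size=2))
        p0 = res.predict_next(inputs, s0.condition)
        p1 = res.predict_next(inputs, s1.condition)
        assert not np.array_equal(p0, p1)
        assert p0.mean() < p1.mean()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            NextFrameForecaster([], tiny_config())

    def test_summary_mentions_config(self):
        rng = np.random.default_rng(0)
        res = train([make_sample(rng)], tiny_config(itr=2, batch_size=1))
        text = res.summary()
        assert "LSTM" in text and "epochs trained  : 2" in text


class TestCheckpoint:
    def test_save_load_round_trip_predictions(self, tmp_path, rng):
        samples = [make_sample(rng, ordinal=i) for i in range(3)]
        res = train(samples, tiny_config(itr=3))
        path = tmp_path / "model.ckpt"
        save_model(res, path)
        back = load_model(path)
        assert back.config == res.config
        assert back.training_log == res.training_log
        for _ in range(5):
            frames = [rng.random((FS, FS)) for _ in range(3)]
            cond = encode_condition(int(rng.integers(0, 16)), 4)
            np.testing.assert_array_equal(
                predict_next(res, frames, cond), predict_next(back, frames, cond)
            )

    def test_corrupted_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "bad.ckpt"
        path.write_bytes(b"this is not a checkpoint")
        with pytest.raises(IncompatibleCheckpointError):
            load_model(path)
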