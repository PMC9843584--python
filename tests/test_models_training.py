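"""Model forward contracts, masking, and training disciplines."""

import numpy as np
import pytest

from ntaug import codon_model as cm
from ntaug import data_pipeline as dp
from ntaug import synthetic_data as sd
from ntaug.augmentation import AugmentationConfig, OnlineAugmentConfig, augment_dataset_offline
from ntaug.dataset import LabeledDataset, LabeledRecord
from ntaug.encoding import build_vocabulary, n_tokens
from ntaug.errors import ConfigError
from ntaug.models_training import (
    ModelConfig,
    TrainConfig,
    build_model,
    predict,
    predict_class,
    train,
)

from conftest import make_regression_dataset


def nt_dataset(n, seed=0, task="regression"):
    rng = np.random.default_rng(seed)
    table = cm.natural_table()
    records = []
    for i in range(n):
        aa = "".join(rng.choice(list(cm.AMINO_ACIDS), size=6))
        nt = cm.reverse_translate(aa, table, "random", rng)
        label = float(rng.normal()) if task == "regression" else float(rng.integers(2))
        records.append(LabeledRecord(f"r{i}", nt, label))
    return LabeledDataset(records, alphabet="nucleotide", task=task)


@pytest.fixture(scope="module")
def landscape_sets():
    """Shared small landscape: train/valid nucleotide sets, trigram scheme."""
    spec = sd.gb1_like_spec(seed=0)
    data = sd.generate_landscape(spec, 600, 4)
    split = dp.split_by_edit_distance(data, dp.SplitSpec(spec.wild_type, 3), seed=0)
    table = cm.natural_table()
    train_nt = augment_dataset_offline(
        split.subset("train"), AugmentationConfig(3, "random", table, seed=0)
    )
    valid_nt = dp.make_test_replicates(
        split.subset("valid"), table, "random", 1, 1
    ).replicates[0]
    return train_nt, valid_nt


class TestForwardContract:
    @pytest.mark.parametrize("family", ["cnn", "transformer"])
    def test_output_shape(self, family):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig(family, "regression", "desk"), vocab, 8)
        data = nt_dataset(7)
        out = model.forward(model.encode(data.sequences), np.random.default_rng(0))
        assert out.shape == (7, 1)

    @pytest.mark.parametrize("family", ["cnn", "transformer"])
    def test_padding_invariance(self, family):
        """Predictions do not depend on how much right-padding a batch carries:
        mixed-length batches and single-sequence batches agree."""
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig(family, "regression", "desk"), vocab, 12)
        rng = np.random.default_rng(0)
        table = cm.natural_table()
        short = cm.reverse_translate("MSKL", table, "random", rng)
        longer = cm.reverse_translate("MSKLWCDERYPA", table, "random", rng)
        alone = predict(model, [short])
        padded = predict(model, [short, longer])
        assert np.allclose(alone[0], padded[0], atol=1e-10)

    def test_classification_sigmoid_range(self):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "classification", "desk"), vocab, 6)
        data = nt_dataset(5, task="classification")
        logits = predict(model, data.sequences)
        prob = 1 / (1 + np.exp(-logits))
        assert ((prob > 0) & (prob < 1)).all()

    def test_cnn_requires_one_hot_capable_scheme(self):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk"), vocab, 6)
        batch = model.encode(["ATGTGGAAA"])
        assert batch.one_hot is not None


class TestPredict:
    def test_empty_input(self):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk"), vocab, 6)
        assert predict(model, []).shape == (0,)

    def test_eval_determinism(self):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("transformer", "regression", "desk"), vocab, 6)
        data = nt_dataset(9)
        a = predict(model, data.sequences)
        b = predict(model, data.sequences)
        assert np.array_equal(a, b)
        assert np.isfinite(a).all()


class TestTraining:
    def test_loss_decreases_on_landscape(self, landscape_sets):
        train_nt, valid_nt = landscape_sets
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk", seed=0), vocab, 9)
        res = train(model, train_nt, valid_nt,
                    TrainConfig(epochs=8, patience=8, batch_size=32, lr=0.01, seed=0))
        assert res.train_loss[-1] < res.train_loss[0]

    def test_desk_learnability_cnn(self, landscape_sets):
        """Desk-preset CNN reaches validation Rho > 0.5 on the synthetic
        landscape — a smoke property of the whole pipeline."""
        train_nt, valid_nt = landscape_sets
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk", seed=0), vocab, 9)
        res = train(model, train_nt, valid_nt,
                    TrainConfig(epochs=20, patience=10, batch_size=32, lr=0.01, seed=0))
        assert max(res.valid_metric) > 0.5

    def test_desk_learnability_transformer(self, landscape_sets):
        train_nt, valid_nt = landscape_sets
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("transformer", "regression", "desk", seed=0), vocab, 9)
        res = train(model, train_nt, valid_nt,
                    TrainConfig(epochs=25, patience=25, batch_size=32, lr=0.01, seed=0,
                                clip_norm=1.0))
        assert max(res.valid_metric) > 0.5

    def test_online_disabled_equals_offline_bitwise(self):
        """Online training with t_aug=1.0 (augmentation never fires) matches
        the plain run bit for bit: same batches, same dropout draws."""
        data = nt_dataset(40, seed=1)
        valid = nt_dataset(10, seed=2)
        vocab = build_vocabulary("nt_trigram")
        ocfg = OnlineAugmentConfig(t_aug=1.0, num_subs=0.25, table=cm.natural_table())
        results = []
        for mode in ("offline", "online"):
            model = build_model(ModelConfig("cnn", "regression", "desk", seed=0), vocab, 6)
            tc = TrainConfig(mode=mode, epochs=4, patience=100, batch_size=8, lr=0.01,
                             seed=0, online_cfg=ocfg if mode == "online" else None)
            results.append(train(model, data, valid, tc))
        assert results[0].train_loss == results[1].train_loss
        assert results[0].valid_loss == results[1].valid_loss

    def test_online_mode_runs_fixed_epochs(self):
        data = nt_dataset(30, seed=3)
        valid = nt_dataset(8, seed=4)
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk", seed=0), vocab, 6)
        ocfg = OnlineAugmentConfig(t_aug=0.5, num_subs=0.25, table=cm.natural_table(), seed=0)
        res = train(model, data, valid,
                    TrainConfig(mode="online", epochs=5, batch_size=8, lr=0.01, seed=0,
                                online_cfg=ocfg))
        assert len(res.train_loss) == 5
        assert res.stopped_epoch == 5

    def test_patience_zero_stops_at_first_non_improvement(self):
        data = nt_dataset(30, seed=5)
        valid = nt_dataset(8, seed=6)
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk", seed=0), vocab, 6)
        res = train(model, data, valid,
                    TrainConfig(epochs=50, patience=0, batch_size=8, lr=0.01, seed=0))
        first_drop = next(
            (i for i in range(1, len(res.valid_metric))
             if res.valid_metric[i] <= max(res.valid_metric[:i])),
            None,
        )
        if first_drop is None:
            assert res.stopped_epoch == 50  # improved every epoch; no stop
        else:
            assert res.stopped_epoch == first_drop + 1

    def test_empty_train_set_rejected(self):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "regression", "desk"), vocab, 6)
        empty = LabeledDataset([], alphabet="nucleotide", task="regression")
        with pytest.raises(ConfigError):
            train(model, empty, empty, TrainConfig(epochs=1))

    def test_online_requires_config(self):
        with pytest.raises(ConfigError):
            TrainConfig(mode="online", online_cfg=None)

    def test_class_weighted_sampling_balances_batches(self):
        data = nt_dataset(100, seed=7, task="classification")
        # force imbalance: 10 positives
        records = [r.with_(label=1.0 if i < 10 else 0.0) for i, r in enumerate(data)]
        data = LabeledDataset(records, alphabet="nucleotide", task="classification")
        valid = nt_dataset(10, seed=8, task="classification")
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "classification", "desk", seed=0), vocab, 6)
        res = train(model, data, valid,
                    TrainConfig(epochs=2, patience=5, batch_size=16, lr=0.001, seed=0,
                                class_weighted_sampling=True))
        assert len(res.train_loss) == 2  # runs without error; balance is statistical

    def test_classification_prediction_threshold(self):
        vocab = build_vocabulary("nt_trigram")
        model = build_model(ModelConfig("cnn", "classification", "desk"), vocab, 6)
        data = nt_dataset(6, task="classification")
        cls = predict_class(model, data.sequences)
        assert set(cls) <= {0, 1}
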