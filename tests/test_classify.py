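import numpy as np
import pytest
from scipy.stats import binom

from orthoclass.classify import (
    ClassifyError,
    LabeledDataset,
    ModelSpec,
    SplitSpec,
    load_model,
    make_dataset,
    one_hot_encode,
    predict,
    save_model,
    split_dataset,
    train_model,
)
from orthoclass.datamodel import ExpressionMatrix, SampleLabels

from conftest import SMALL_CNN


def _dataset(n_per_class=10, n_features=24, classes=("A", "B"), seed=0, separation=3.0):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for k, c in enumerate(classes):
        center = np.zeros(n_features)
        center[k * 3 : k * 3 + 3] = separation
        X.append(rng.normal(center, 1.0, size=(n_per_class, n_features)))
        labels += [c] * n_per_class
    return LabeledDataset(
        X=np.vstack(X),
        labels=labels,
        classes=list(classes),
        feature_ids=tuple(f"g{i}" for i in range(n_features)),
    )


class TestOneHot:
    def test_definition(self):
        out = one_hot_encode(["A", "B", "A"], ["A", "B"])
        assert np.array_equal(out, [[1, 0], [0, 1], [1, 0]])

    def test_rows_sum_to_one(self):
        out = one_hot_encode(list("ABCABC"), ["A", "B", "C"])
        assert np.array_equal(out.sum(axis=1), np.ones(6))

    def test_argmax_round_trip(self):
        labels = ["B", "C", "A", "C"]
        classes = ["A", "B", "C"]
        out = one_hot_encode(labels, classes)
        assert [classes[i] for i in out.argmax(axis=1)] == labels

    def test_unseen_label_named(self):
        with pytest.raises(ClassifyError, match="'Z'"):
            one_hot_encode(["A", "Z"], ["A", "B"])


class TestSplit:
    def test_default_sizes_80_10_10(self):
        ds = _dataset(n_per_class=50, classes=("A", "B"))
        train, val, test = split_dataset(ds, SplitSpec(seed=1))
        assert (train.n_samples, val.n_samples, test.n_samples) == (80, 10, 10)

    def test_same_seed_identical(self):
        ds = _dataset(n_per_class=20, classes=("A", "B", "C"))
        a = split_dataset(ds, SplitSpec(seed=7))
        b = split_dataset(ds, SplitSpec(seed=7))
        for x, y in zip(a, b):
            assert x.sample_ids == y.sample_ids

    def test_partition_property(self):
        ds = _dataset(n_per_class=17, classes=("A", "B", "C"))
        train, val, test = split_dataset(ds, SplitSpec(seed=2))
        ids = train.sample_ids + val.sample_ids + test.sample_ids
        assert len(ids) == len(set(ids)) == ds.n_samples
        assert set(ids) == set(ds.sample_ids)

    def test_stratified_proportions_within_one(self):
        ds = _dataset(n_per_class=30, classes=("A", "B", "C"))
        train, val, test = split_dataset(ds, SplitSpec(seed=3))
        for part, frac in ((train, 0.8), (val, 0.1), (test, 0.1)):
            for c in ("A", "B", "C"):
                assert abs(part.labels.count(c) - frac * 30) <= 1

    def test_bad_fractions_rejected(self):
        with pytest.raises(ClassifyError):
            SplitSpec(fractions=(0.7, 0.2, 0.2))

    def test_small_class_named(self):
        ds = _dataset(n_per_class=10, classes=("A", "B"))
        tiny = LabeledDataset(
            X=np.vstack([ds.X, np.zeros((2, ds.n_features))]),
            labels=ds.labels + ["C", "C"],
            classes=["A", "B", "C"],
            feature_ids=ds.feature_ids,
        )
        with pytest.raises(ClassifyError, match="'C'"):
            split_dataset(tiny, SplitSpec(seed=0))

    def test_unstratified_mode(self):
        ds = _dataset(n_per_class=50, classes=("A", "B"))
        train, val, test = split_dataset(ds, SplitSpec(seed=1, stratified=False))
        assert (train.n_samples, val.n_samples, test.n_samples) == (80, 10, 10)


class TestMakeDataset:
    def test_requires_log10_tpm(self):
        m = ExpressionMatrix(["g1"], ["s1"], [[2.0]], "counts", "human")
        with pytest.raises(ClassifyError):
            make_dataset(m, SampleLabels({"s1": "A"}))

    def test_transposes_and_orders(self):
        m = ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2"], [[1.0, 2.0], [3.0, 4.0]], "log10_tpm", "human"
        )
        ds = make_dataset(m, SampleLabels({"s1": "A", "s2": "B"}))
        assert ds.X.shape == (2, 2)
        assert np.array_equal(ds.X[0], [1.0, 3.0])
        assert ds.classes == ["A", "B"]


class TestTrainErrors:
    def test_single_class_rejected(self):
        ds = _dataset(classes=("A",))
        with pytest.raises(ClassifyError):
            train_model(ModelSpec(kind="random_forest"), ds)

    def test_empty_training_rejected(self):
        ds = _dataset().subset([])
        with pytest.raises(ClassifyError):
            train_model(ModelSpec(kind="random_forest"), ds)

    def test_mismatched_val_rejected(self):
        train = _dataset(classes=("A", "B"))
        val = _dataset(classes=("A", "C"), seed=1)
        with pytest.raises(ClassifyError):
            train_model(ModelSpec(kind="random_forest"), train, val)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ClassifyError):
            ModelSpec(kind="svm")


class TestBaselines:
    @pytest.mark.parametrize("kind", ["random_forest", "logistic_regression"])
    def test_separable_data_learned(self, kind):
        train = _dataset(n_per_class=30, seed=0)
        test = _dataset(n_per_class=10, seed=99)
        model = train_model(ModelSpec(kind=kind, seed=0), train)
        _, pred = predict(model, test)
        assert np.mean([p == t for p, t in zip(pred, test.labels)]) >= 0.9

    @pytest.mark.parametrize("kind", ["random_forest", "logistic_regression"])
    def test_duplicating_training_samples_is_noop(self, kind):
        train = _dataset(n_per_class=25, seed=1, separation=4.0)
        doubled = train.subset(list(range(train.n_samples)) * 2)
        test = _dataset(n_per_class=10, seed=123, separation=4.0)
        m1 = train_model(ModelSpec(kind=kind, seed=5), train)
        m2 = train_model(ModelSpec(kind=kind, seed=5), doubled)
        _, p1 = predict(m1, test)
        _, p2 = predict(m2, test)
        assert p1 == p2

    def test_probability_rows_sum_to_one(self):
        train = _dataset(n_per_class=15, classes=("A", "B", "C"))
        model = train_model(ModelSpec(kind="random_forest", seed=0), train)
        proba, _ = predict(model, train)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_predict_is_pure(self):
        train = _dataset(n_per_class=15)
        model = train_model(ModelSpec(kind="logistic_regression", seed=0), train)
        p1, l1 = predict(model, train)
        p2, l2 = predict(model, train)
        assert np.array_equal(p1, p2)
        assert l1 == l2


class TestCnn:
    def test_cnn_beats_accuracy_bar_with_lr_oracle(self, separable):
        # held-out accuracy >= 0.95 where the logistic-regression oracle
        # reaches >= 0.9 on the same data
        test = separable["test"]
        _, pred_cnn = predict(separable["cnn"], test)
        _, pred_lr = predict(separable["lr"], test)
        acc_cnn = np.mean([p == t for p, t in zip(pred_cnn, test.labels)])
        acc_lr = np.mean([p == t for p, t in zip(pred_lr, test.labels)])
        assert acc_lr >= 0.9
        assert acc_cnn >= 0.95

    def test_training_set_self_accuracy(self, separable):
        train = separable["train"]
        _, pred = predict(separable["cnn"], train)
        assert np.mean([p == t for p, t in zip(pred, train.labels)]) >= 0.95

    def test_probability_rows_sum_to_one(self, separable):
        proba, _ = predict(separable["cnn"], separable["test"])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_under_seed(self):
        train = _dataset(n_per_class=20, n_features=40, seed=2)
        val = _dataset(n_per_class=5, n_features=40, seed=3)
        spec = ModelSpec(
            kind="cnn1d", conv_filters=(4,), kernel_size=5, pool_size=2,
            dense_units=8, epochs=4, seed=9,
        )
        p1, _ = predict(train_model(spec, train, val), val)
        p2, _ = predict(train_model(spec, train, val), val)
        assert np.array_equal(p1, p2)

    def test_label_permutation_gives_chance(self, separable):
        # training on permuted labels must not beat the binomial 99% bound
        rng = np.random.default_rng(0)
        train, val, test = separable["train"], separable["val"], separable["test"]
        perm_train = LabeledDataset(
            X=train.X,
            labels=[train.labels[i] for i in rng.permutation(train.n_samples)],
            classes=train.classes,
            feature_ids=train.feature_ids,
        )
        spec = ModelSpec(**{**SMALL_CNN, "epochs": 10}, seed=1)
        model = train_model(spec, perm_train, val)
        _, pred = predict(model, test)
        hits = sum(p == t for p, t in zip(pred, test.labels))
        upper = binom.ppf(0.995, test.n_samples, 1.0 / len(test.classes))
        assert hits <= upper


class TestFingerprint:
    def test_mismatch_rejected(self, separable):
        test = separable["test"]
        wrong = LabeledDataset(
            X=test.X,
            labels=test.labels,
            classes=test.classes,
            feature_ids=tuple(f"other{i}" for i in range(test.n_features)),
        )
        with pytest.raises(ClassifyError, match="fingerprint"):
            predict(separable["cnn"], wrong)

    def test_unprojected_matrix_rejected(self, separable):
        # canine-side matrix straight from the simulator (not projected)
        from orthoclass.normalize import counts_to_tpm, log10_transform
        from orthoclass.simulate import SPECIES_B, generate_cohort, generate_ortholog_table

        config = separable["config"]
        _, _, ann_b = generate_ortholog_table(config)
        matrix_b, _, _ = generate_cohort(config, SPECIES_B)
        log_b = log10_transform(counts_to_tpm(matrix_b, ann_b))
        with pytest.raises(ClassifyError, match="fingerprint"):
            predict(separable["cnn"], log_b)


class TestSaveLoad:
    def test_round_trip_predictions(self, tmp_path, separable):
        probe = separable["test"]
        save_model(separable["cnn"], tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        p1, _ = predict(separable["cnn"], probe)
        p2, _ = predict(loaded, probe)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_missing_fingerprint_file(self, tmp_path):
        with pytest.raises(ClassifyError, match="fingerprint"):
            load_model(tmp_path)

    def test_corrupted_payload_errors(self, tmp_path, separable):
        save_model(separable["lr"], tmp_path / "model")
        (tmp_path / "model" / "model.joblib").write_bytes(b"garbage")
        with pytest.raises(ClassifyError, match="cannot load"):
            load_model(tmp_path / "model")

    def test_loaded_model_still_guards_features(self, tmp_path, separable):
        save_model(separable["lr"], tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        bad = np.zeros((2, 3))
        with pytest.raises(ClassifyError):
            predict(loaded, bad)
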