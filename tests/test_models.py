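"""Classifier training, contact-map prediction and model persistence."""

import numpy as np
import pytest

from attnprobe import (
    PredictorKind,
    PredictorSpec,
    load_model,
    predict_contact_map,
    save_model,
    train_cnn,
    train_tabular,
)
from attnprobe.attention import AttentionStack
from attnprobe.errors import (
    ConfigError,
    FeatureError,
    LoadError,
    TrainingError,
)
from attnprobe.features import PairDataset, balance_dataset, build_pair_dataset
from attnprobe.metrics import binary_macro_f1
from attnprobe.models import TrainedPredictor, predict_pairs
from attnprobe.contacts import eligible_pairs
from attnprobe.synthetic import SyntheticSpec, gen_corpus
from attnprobe.attention import process_stack


def _table(features, labels):
    n = len(labels)
    ds = PairDataset(
        molecule_ids=np.array(["m"] * n, dtype=object),
        i=np.zeros(n, dtype=np.int64),
        j=np.arange(5, n + 5, dtype=np.int64),
        features=np.asarray(features, dtype=float),
        labels=np.asarray(labels, dtype=np.int8),
        feature_names=[f"layer0_head{k}" for k in range(np.shape(features)[1])],
        balanced=True,
    )
    return ds


class _ConstantModel:
    """predict_proba stub emitting a fixed contact probability."""

    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, x):
        return np.column_stack([np.full(len(x), 1 - self.p), np.full(len(x), self.p)])


def _wrap(est, n_layers=1, n_heads=2):
    return TrainedPredictor(
        spec=PredictorSpec(kind="logistic"),
        model=est,
        feature_names=[f"layer{l}_head{h}" for l in range(n_layers) for h in range(n_heads)],
    )


class TestTrainTabular:
    def test_separable_features_learned_by_logistic(self, rng):
        labels = rng.integers(0, 2, size=400)
        features = np.column_stack(
            [labels + rng.normal(0, 0.01, 400), rng.normal(size=400)]
        )
        # equalize classes exactly
        ds = balance_dataset(_table(features, labels), seed=0)
        model = train_tabular(ds, PredictorSpec(kind="logistic", seed=0))
        pred = (predict_pairs(model, ds.features) >= 0.5).astype(int)
        assert (pred == ds.labels).mean() > 0.99

    def test_noise_features_score_at_chance_on_heldout(self, rng):
        n = 1200
        labels = np.repeat([0, 1], n // 2)
        features = rng.normal(size=(n, 6))
        ds = _table(features[: n // 2 * 2], labels)
        model = train_tabular(ds, PredictorSpec(kind="logistic", seed=0))
        held_f = rng.normal(size=(800, 6))
        held_y = np.repeat([0, 1], 400)
        pred = (predict_pairs(model, held_f) >= 0.5).astype(int)
        assert 0.45 <= binary_macro_f1(held_y, pred) <= 0.55

    @pytest.mark.parametrize(
        "kind", ["logistic", "decision_tree", "random_forest", "gradient_boosting"]
    )
    def test_same_seed_gives_identical_predictions(self, kind, rng):
        labels = np.repeat([0, 1], 60)
        features = rng.normal(size=(120, 4)) + labels[:, None] * 0.5
        ds = _table(features, labels)
        p1 = predict_pairs(
            train_tabular(ds, PredictorSpec(kind=kind, seed=7)), features
        )
        p2 = predict_pairs(
            train_tabular(ds, PredictorSpec(kind=kind, seed=7)), features
        )
        assert np.array_equal(p1, p2)

    def test_empty_dataset_rejected(self):
        ds = _table(np.empty((0, 2)), np.empty(0, dtype=int))
        with pytest.raises(TrainingError):
            train_tabular(ds, PredictorSpec(kind="logistic"))

    def test_unbalanced_dataset_rejected(self):
        ds = _table(np.random.default_rng(0).random((10, 2)), [0] * 8 + [1] * 2)
        ds.balanced = False
        with pytest.raises(TrainingError):
            train_tabular(ds, PredictorSpec(kind="logistic"))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PredictorSpec(kind="svm")


class TestPredictContactMap:
    def _stack(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return AttentionStack(
            molecule_id="m", weights=rng.normal(size=(1, 2, n, n)), processed=True
        )

    def test_always_positive_model_fills_off_band(self):
        stack = self._stack()
        pm = predict_contact_map(_wrap(_ConstantModel(1.0)), stack, window=4)
        ii, jj = eligible_pairs(stack.n, 4)
        assert (pm.binary.matrix[ii, jj] == 1).all()
        assert pm.binary.exclusion_window == 4

    def test_always_negative_model_gives_empty_map(self):
        pm = predict_contact_map(_wrap(_ConstantModel(0.0)), self._stack(), window=4)
        assert pm.binary.matrix.sum() == 0

    def test_probability_map_symmetric_and_band_zero(self):
        pm = predict_contact_map(_wrap(_ConstantModel(0.7)), self._stack(), window=4)
        assert np.array_equal(pm.prob, pm.prob.T)
        i, j = np.indices(pm.prob.shape, sparse=True)
        assert (pm.prob[np.abs(i - j) <= 4] == 0).all()
        assert ((pm.prob >= 0) & (pm.prob <= 1)).all()

    def test_feature_layout_mismatch_rejected(self):
        model = _wrap(_ConstantModel(1.0), n_layers=2, n_heads=2)
        with pytest.raises(FeatureError):
            predict_contact_map(model, self._stack(), window=4)

    def test_signal_only_corpus_recovers_planted_map(self):
        corpus = gen_corpus(
            SyntheticSpec(n_molecules=21, length_range=(30, 50), alpha=1.0, seed=5)
        )
        proc = [process_stack(s) for s in corpus.stacks]
        w = corpus.spec.window
        ds = balance_dataset(
            build_pair_dataset(proc[:20], corpus.maps[:20], w), seed=0
        )
        model = train_tabular(ds, PredictorSpec(kind="logistic", seed=0))
        pm = predict_contact_map(model, proc[20], w)
        assert np.array_equal(pm.binary.matrix, corpus.maps[20].matrix)


@pytest.fixture(scope="module")
def corpora():
    out = {}
    for alpha in (1.0, 0.0):
        corpus = gen_corpus(
            SyntheticSpec(n_molecules=14, length_range=(30, 50), alpha=alpha, seed=7)
        )
        proc = [process_stack(s) for s in corpus.stacks]
        out[alpha] = (corpus, proc)
    return out


class TestCNN:
    def _heldout_f1(self, corpus, proc):
        w = corpus.spec.window
        model = train_cnn(
            proc[:10], corpus.maps[:10], PredictorSpec(kind="cnn", seed=0), window=w
        )
        f1s = []
        for stack, cmap in zip(proc[10:], corpus.maps[10:]):
            pm = predict_contact_map(model, stack, w)
            ii, jj = eligible_pairs(cmap.n, w)
            f1s.append(binary_macro_f1(cmap.matrix[ii, jj], pm.binary.matrix[ii, jj]))
        return float(np.mean(f1s)), model

    def test_signal_only_corpus_reaches_high_per_pixel_f1(self, corpora):
        f1, _ = self._heldout_f1(*corpora[1.0])
        assert f1 >= 0.9

    def test_noise_corpus_scores_at_chance(self, corpora):
        f1, _ = self._heldout_f1(*corpora[0.0])
        assert abs(f1 - 0.5) <= 0.05

    def test_output_map_is_symmetric(self, corpora):
        corpus, proc = corpora[1.0]
        _, model = self._heldout_f1(corpus, proc)
        pm = predict_contact_map(model, proc[-1], corpus.spec.window)
        assert np.array_equal(pm.prob, pm.prob.T)

    def test_wrong_kind_rejected(self):
        with pytest.raises(ConfigError):
            train_cnn([], [], PredictorSpec(kind="logistic"))


class TestPersistence:
    def _trained(self, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], 40)
        features = rng.normal(size=(80, 4)) + labels[:, None]
        return train_tabular(
            _table(features, labels), PredictorSpec(kind="logistic", seed=seed)
        ), features

    def test_roundtrip_preserves_predictions_and_provenance(self, tmp_path):
        model, features = self._trained()
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(
            predict_pairs(model, features), predict_pairs(back, features)
        )
        assert back.provenance["dataset_hash"] == model.provenance["dataset_hash"]
        assert back.spec.kind is PredictorKind.LOGISTIC

    def test_corrupted_file_raises_load_error(self, tmp_path):
        path = tmp_path / "model.joblib"
        path.write_bytes(b"not a model")
        with pytest.raises(LoadError):
            load_model(path)

    def test_foreign_payload_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "thing.joblib"
        joblib.dump({"unrelated": 1}, path)
        with pytest.raises(LoadError):
            load_model(path)
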