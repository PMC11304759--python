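"""Query mood model: presence features, label augmentation, scoring, AUC."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from moodpulse import qmm


def _qlog(rows):
    """rows: (user, timestamp, tokens)"""
    return pd.DataFrame(rows, columns=["user_id", "timestamp", "tokens"])


class TestQueryFeatures:
    def test_presence_only_never_counts(self):
        q = _qlog([(0, "2020-01-06 09:05", ["a", "b"]),
                   (0, "2020-01-06 10:30", ["a"])])
        fs = qmm.build_query_features(q, min_frequency=1)
        assert len(fs) == 1  # both events in frame [09:00, 12:00)
        x = fs.X.toarray()[0]
        assert dict(zip(fs.vocabulary, x)) == {"a": 1.0, "b": 1.0}

    def test_frames_without_queries_absent(self):
        q = _qlog([(0, "2020-01-06 09:05", ["a"])])
        fs = qmm.build_query_features(q, min_frequency=1)
        assert len(fs) == 1

    def test_min_frequency_pruning(self):
        # 'rare' appears in 1 frame; 'common' in 3 distinct frames
        q = _qlog([
            (0, "2020-01-06 00:05", ["common", "rare"]),
            (0, "2020-01-06 03:05", ["common"]),
            (1, "2020-01-06 00:05", ["common"]),
            (1, "2020-01-06 06:05", ["other"]),
            (2, "2020-01-06 09:05", ["other"]),
        ])
        fs = qmm.build_query_features(q, min_frequency=3)
        assert fs.vocabulary == ["common"]

    def test_empty_vocabulary_rejected(self):
        q = _qlog([(0, "2020-01-06 00:05", ["once"])])
        with pytest.raises(ValueError, match="vocabulary"):
            qmm.build_query_features(q, min_frequency=5)


def _frame_set(n, vocab=("a", "b"), seed=0, start="2020-01-06"):
    r = np.random.default_rng(seed)
    frames = pd.date_range(start, periods=n, freq="3h")
    X = sp.csr_matrix((r.random((n, len(vocab))) < 0.5).astype(float))
    idx = pd.DataFrame({"user_id": 0, "frame_start": frames})
    return qmm.QueryFrameSet(X=X, vocabulary=list(vocab), index=idx)


class TestAugmentation:
    def _ann(self, frames, likert):
        return pd.DataFrame({
            "user_id": 0,
            "timestamp": [f + pd.Timedelta(minutes=10) for f in frames],
            "likert": likert})

    def _smm(self, frames, cls):
        return pd.DataFrame({"user_id": 0, "frame_start": frames,
                             "predicted_class": cls})

    def test_annotation_wins_over_smm(self):
        fs = _frame_set(4)
        frames = fs.index["frame_start"]
        ann = self._ann(frames[:2], [7, 1])
        pred = self._smm(frames, [0, 0, 1, 1])
        lab = qmm.augment_labels(fs, ann, pred)
        assert list(lab.labels) == [1, 0, 1, 1]
        assert list(lab.source) == ["annotation", "annotation", "smm", "smm"]

    def test_no_annotations_all_smm(self):
        fs = _frame_set(4)
        pred = self._smm(fs.index["frame_start"], [1, 0, 1, 0])
        lab = qmm.augment_labels(fs, None, pred)
        assert lab.n_annotation == 0 and lab.n_smm == 4

    def test_uncovered_frames_counted_excluded(self):
        fs = _frame_set(5)
        ann = self._ann(fs.index["frame_start"][:1], [6])
        pred = self._smm(fs.index["frame_start"][1:3], [0, 1])
        lab = qmm.augment_labels(fs, ann, pred)
        assert lab.n_excluded == 2
        assert len(lab.labels) == 3

    def test_full_annotation_coverage_makes_augmentation_noop(self):
        fs = _frame_set(6)
        ann = self._ann(fs.index["frame_start"], [7, 1, 6, 2, 7, 1])
        pred = self._smm(fs.index["frame_start"], [0, 1, 0, 1, 0, 1])
        with_smm = qmm.augment_labels(fs, ann, pred)
        without = qmm.augment_labels(fs, ann, None)
        np.testing.assert_array_equal(with_smm.labels, without.labels)
        assert with_smm.n_smm == 0

    def test_half_coverage_doubles_label_count(self):
        fs = _frame_set(200, seed=1)
        frames = fs.index["frame_start"]
        keep = np.arange(200) % 2 == 0
        ann = self._ann(frames[keep], [7 if i % 4 == 0 else 1
                                       for i in range(keep.sum() * 2) if i % 2 == 0])
        pred = self._smm(frames, np.zeros(200, dtype=int))
        n_without = len(qmm.augment_labels(fs, ann, None).labels)
        n_with = len(qmm.augment_labels(fs, ann, pred).labels)
        assert n_with == 200 and n_without == 100
        assert n_with == 2 * n_without


class TestTraining:
    def test_predictive_token_dominant_weight(self):
        rng = np.random.default_rng(0)
        n = 400
        X = (rng.random((n, 3)) < 0.5).astype(float)
        y = X[:, 1].astype(int)  # token 'b' decides the label
        model = qmm.train_qmm(sp.csr_matrix(X), y, ["a", "b", "c"], seed=0)
        assert np.argmax(np.abs(model.weights)) == 1
        assert model.weights[1] > 0

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        X = (rng.random((300, 4)) < 0.4).astype(float)
        logits = X @ np.array([1.0, -1.0, 0.5, 0.0]) - 0.2
        y = (rng.random(300) < 1 / (1 + np.exp(-logits))).astype(int)
        m1 = qmm.train_qmm(sp.csr_matrix(X), y, list("abcd"), seed=0)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        m2 = qmm.train_qmm(sp.csr_matrix(X2), y2, list("abcd"), seed=0)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-4)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-4)

    def test_independent_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        n = 5000
        X = sp.csr_matrix((rng.random((n, 50)) < 0.2).astype(float))
        y = rng.integers(0, 2, n)
        train = np.arange(n) < n // 2
        model = qmm.train_qmm(X[train], y[train], [f"t{i}" for i in range(50)], seed=0)
        rep = qmm.evaluate_auc(qmm.score_mood(model, X[~train]), y[~train])
        assert abs(rep.auc - 0.5) < 0.05

    def test_degenerate_inputs_rejected(self):
        X = sp.csr_matrix(np.eye(4))
        with pytest.raises(ValueError, match="single-class"):
            qmm.train_qmm(X, np.ones(4), list("abcd"))
        with pytest.raises(ValueError, match="all-zero"):
            qmm.train_qmm(sp.csr_matrix((4, 4)), np.array([0, 1, 0, 1]), list("abcd"))


class TestScoring:
    def _model(self):
        return qmm.QMMModel(weights=np.array([0.5, -1.0, 2.0]), intercept=0.25,
                            vocabulary=["a", "b", "c"], l2_lambda=1e-4,
                            n_train=10, seed=0)

    def test_all_zeros_gives_intercept(self):
        m = self._model()
        assert qmm.score_mood(m, np.zeros((1, 3)))[0] == pytest.approx(0.25)

    def test_hand_summed_score(self):
        m = self._model()
        x = np.array([[1.0, 0.0, 1.0]])  # tokens a and c
        assert qmm.score_mood(m, x)[0] == pytest.approx(0.25 + 0.5 + 2.0)

    def test_positive_weight_token_increases_score(self):
        m = self._model()
        base = qmm.score_mood(m, np.array([[1.0, 0.0, 0.0]]))[0]
        more = qmm.score_mood(m, np.array([[1.0, 0.0, 1.0]]))[0]
        assert more > base

    def test_vocabulary_mismatch_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            qmm.score_mood(self._model(), np.zeros((1, 5)))


class TestAUC:
    def test_perfect_separation(self):
        rep = qmm.evaluate_auc(np.array([-2.0, -1.0, 1.0, 2.0]),
                               np.array([0, 0, 1, 1]))
        assert rep.auc == 1.0

    def test_shuffled_scores_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 2000)
        rep = qmm.evaluate_auc(rng.normal(size=2000), y)
        assert abs(rep.auc - 0.5) < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            qmm.evaluate_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.sampled_from(["exp", "cube", "affine"]))
    def test_auc_invariant_to_monotone_transform(self, seed, kind):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * 10)
        s = rng.normal(size=20)
        base = qmm.evaluate_auc(s, y).auc
        t = {"exp": np.exp(s), "cube": s ** 3, "affine": 3 * s + 7}[kind]
        assert qmm.evaluate_auc(t, y).auc == pytest.approx(base)
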