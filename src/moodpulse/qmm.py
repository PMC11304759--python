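"""Query Mood Model: logistic regression on binary query-presence features.

Each (user, 3-hour frame) with at least one search event becomes a row whose
feature vector x has x_k = 1 iff vocabulary token k was searched in that
frame — presence only, never counts; a multi-token query sets each of its
tokens' indicators.

The model is fit by L2-regularized logistic regression, but the mood score
reported downstream is the *unbounded linear predictor*
``y = intercept + sum_k w_k x_k`` (never the sigmoid output): the nationwide
score is an average of these unbounded values. The regularization strength
is per-sample (``C = 1 / (n * l2_lambda)``), so duplicating every training
row leaves the fitted decision function unchanged.

Label augmentation (the two-step scheme): a frame's training label comes
from its ESM annotation when one exists; frames without an annotation
receive the sensor model's predicted class. Evaluation labels are always
annotation-sourced only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._frames import frame_floor
from .smm import binarize_likert

__all__ = [
    "QueryFrameSet",
    "LabeledQueryFrames",
    "QMMModel",
    "AUCReport",
    "build_query_features",
    "augment_labels",
    "train_qmm",
    "score_mood",
    "evaluate_auc",
]


@dataclass
class QueryFrameSet:
    """Binary query-presence design matrix with its (user, frame) index.

    ``X`` is CSR with one row per (user, frame) that had >= 1 query event and
    one column per vocabulary token; entries are {0, 1}.
    """

    X: sp.csr_matrix
    vocabulary: list[str]
    index: pd.DataFrame  # columns user_id, frame_start

    def __len__(self) -> int:
        return self.X.shape[0]


def build_query_features(queries: pd.DataFrame, min_frequency: int = 5,
                         vocabulary: list[str] | None = None) -> QueryFrameSet:
    """Turn a query-event log into per-frame binary presence vectors.

    ``queries`` needs columns user_id, timestamp, tokens (list of str).
    When ``vocabulary`` is None it is built from the data, keeping tokens that
    appear in at least ``min_frequency`` distinct (user, frame) cells; pass an
    existing vocabulary to featurize test data consistently. Tokens outside
    the vocabulary are ignored. Frames with no in-vocabulary token still get
    a row (all zeros) as long as they had an event.
    """
    if len(queries) == 0:
        raise ValueError("empty query log")
    q = queries.copy()
    q["frame_start"] = frame_floor(q["timestamp"]).to_numpy()

    # explode to (user, frame, token), then dedupe: presence only
    rows = q[["user_id", "frame_start", "tokens"]].explode("tokens")
    rows = rows.rename(columns={"tokens": "token"})
    rows = rows.dropna(subset=["token"]).drop_duplicates()

    frames = q[["user_id", "frame_start"]].drop_duplicates().reset_index(drop=True)
    frame_key = pd.MultiIndex.from_frame(frames)
    frame_pos = pd.Series(np.arange(len(frames)), index=frame_key)

    if vocabulary is None:
        counts = rows["token"].value_counts()
        vocabulary = sorted(counts.index[counts >= min_frequency])
        if not vocabulary:
            raise ValueError(
                f"empty vocabulary after pruning tokens seen in < {min_frequency} frames")
    vocab_pos = {t: j for j, t in enumerate(vocabulary)}

    keep = rows["token"].isin(vocab_pos)
    rows = rows.loc[keep]
    i = frame_pos.reindex(
        pd.MultiIndex.from_frame(rows[["user_id", "frame_start"]])).to_numpy()
    j = rows["token"].map(vocab_pos).to_numpy()
    X = sp.csr_matrix(
        (np.ones(len(i)), (i, j)), shape=(len(frames), len(vocabulary)))
    X.data = np.minimum(X.data, 1.0)  # paranoia: presence only
    return QueryFrameSet(X=X, vocabulary=list(vocabulary), index=frames)


@dataclass
class LabeledQueryFrames:
    """Query frames with resolved training labels and their provenance."""

    frames: QueryFrameSet
    labels: np.ndarray  # binary {0, 1}, aligned with frames rows that are kept
    source: np.ndarray  # 'annotation' | 'smm' per kept row
    kept: np.ndarray  # boolean mask into frames.index: rows with a usable label
    n_excluded: int  # frames with neither annotation nor SMM prediction (or neutral)

    @property
    def n_annotation(self) -> int:
        return int((self.source == "annotation").sum())

    @property
    def n_smm(self) -> int:
        return int((self.source == "smm").sum())

    @property
    def X(self) -> sp.csr_matrix:
        return self.frames.X[self.kept]


def annotation_frame_labels(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-(user, frame) binary label from ESM annotations.

    Multiple annotations in a frame are averaged and rounded half-to-even
    before binarization; neutral (level 4) frames get NaN.
    """
    ann = annotations.copy()
    ann["frame_start"] = frame_floor(ann["timestamp"]).to_numpy()
    g = ann.groupby(["user_id", "frame_start"])["likert"].mean()
    lik = np.rint(g.to_numpy())
    out = g.reset_index()
    out["label"] = binarize_likert(lik)
    return out[["user_id", "frame_start", "label"]]


def augment_labels(frames: QueryFrameSet, annotations: pd.DataFrame | None,
                   smm_predictions: pd.DataFrame | None) -> LabeledQueryFrames:
    """Resolve a training label for each query frame.

    Annotation-derived labels win wherever an annotation exists in the frame
    (the sensor model only supplements *missing* labels). Neutral-annotated
    frames are excluded outright. Frames with neither an annotation nor an
    SMM prediction are excluded and counted in ``n_excluded``.

    ``smm_predictions`` needs columns user_id, frame_start, predicted_class
    (binary 0/1); pass None for the annotation-only (no augmentation) variant.
    """
    idx = frames.index.copy()
    label = np.full(len(idx), np.nan)
    source = np.array(["none"] * len(idx), dtype=object)
    annotated = np.zeros(len(idx), dtype=bool)

    if annotations is not None and len(annotations):
        ann_lab = annotation_frame_labels(annotations)
        merged = idx.merge(ann_lab, on=["user_id", "frame_start"], how="left",
                           indicator=True)
        has_ann = (merged["_merge"] == "both").to_numpy()
        annotated = has_ann
        lab = merged["label"].to_numpy()
        usable = has_ann & np.isfinite(lab)
        label[usable] = lab[usable]
        source[usable] = "annotation"

    if smm_predictions is not None and len(smm_predictions):
        pred = smm_predictions[["user_id", "frame_start", "predicted_class"]].copy()
        pred["frame_start"] = pd.to_datetime(pred["frame_start"])
        merged = idx.merge(pred, on=["user_id", "frame_start"], how="left")
        smm_lab = merged["predicted_class"].to_numpy(dtype=float)
        fill = (~annotated) & np.isfinite(smm_lab)
        label[fill] = smm_lab[fill]
        source[fill] = "smm"

    kept = np.isfinite(label)
    return LabeledQueryFrames(
        frames=frames, labels=label[kept].astype(int), source=source[kept],
        kept=kept, n_excluded=int((~kept).sum()))


@dataclass
class QMMModel:
    """Fitted query mood model: per-token weights and intercept."""

    weights: np.ndarray
    intercept: float
    vocabulary: list[str]
    l2_lambda: float
    n_train: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "vocabulary": self.vocabulary,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "l2_lambda": self.l2_lambda,
            "n_train": self.n_train,
            "seed": self.seed,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "QMMModel":
        d = json.loads(Path(path).read_text())
        return cls(weights=np.asarray(d["weights"]), intercept=d["intercept"],
                   vocabulary=d["vocabulary"], l2_lambda=d["l2_lambda"],
                   n_train=d["n_train"], seed=d["seed"])


def train_qmm(X: sp.spmatrix | np.ndarray, y: np.ndarray,
              vocabulary: list[str], l2_lambda: float = 1e-4,
              seed: int = 0) -> QMMModel:
    """Fit the logistic-regression query mood model.

    ``l2_lambda`` is the per-sample ridge penalty (objective:
    mean log-loss + l2_lambda/2 * ||w||^2), which makes the fit invariant to
    duplicating the training set.
    """
    y = np.asarray(y)
    n = X.shape[0]
    if n == 0:
        raise ValueError("no training rows")
    if X.shape[1] != len(vocabulary):
        raise ValueError("design matrix width != vocabulary size")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"single-class training labels ({classes.tolist()})")
    nnz = X.nnz if sp.issparse(X) else np.count_nonzero(X)
    if nnz == 0:
        raise ValueError("all-zero feature matrix")

    clf = LogisticRegression(
        C=1.0 / (n * l2_lambda), solver="lbfgs",
        max_iter=2000, tol=1e-8, random_state=seed)
    clf.fit(X, y)
    return QMMModel(weights=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]),
                    vocabulary=list(vocabulary), l2_lambda=l2_lambda,
                    n_train=n, seed=seed)


def score_mood(model: QMMModel, frames: QueryFrameSet | sp.spmatrix | np.ndarray) -> np.ndarray:
    """Unbounded mood score y = intercept + sum_k w_k x_k per frame.

    A probability-scale output is available via ``scipy.special.expit`` of
    this value, but the aggregation pipeline always uses the linear predictor.
    """
    if isinstance(frames, QueryFrameSet):
        if frames.vocabulary != model.vocabulary:
            raise ValueError("vocabulary mismatch between model and frames")
        X = frames.X
    else:
        X = frames
        if X.shape[1] != len(model.vocabulary):
            raise ValueError(
                f"feature width {X.shape[1]} != vocabulary size {len(model.vocabulary)}")
    return np.asarray(X @ model.weights).ravel() + model.intercept


@dataclass
class AUCReport:
    """ROC-AUC of the mood score against annotation-sourced binary labels."""

    auc: float
    n_train_labels: int
    n_test: int
    condition: str  # 'with_smm' | 'without_smm'

    def to_dict(self) -> dict:
        return {"auc": self.auc, "n_train_labels": self.n_train_labels,
                "n_test": self.n_test, "condition": self.condition}


def evaluate_auc(scores: np.ndarray, labels: np.ndarray, condition: str = "",
                 n_train_labels: int = 0) -> AUCReport:
    """Rank-based ROC-AUC of unbounded mood scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("test labels contain a single class; AUC undefined")
    return AUCReport(auc=float(roc_auc_score(labels, scores)),
                     n_train_labels=n_train_labels, n_test=len(labels),
                     condition=condition)
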