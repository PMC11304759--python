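"""Sensor Mood Model: per-frame mood classification from smartphone features.

The SMM is a single pooled classifier over 3-hour frame features, trained on
frames carrying an ESM self-report, and applied to every frame so its
predictions can stand in for missing labels when the query mood model is
trained (the two-step scheme).

Class scheme: by default the 7-level Likert self-report is binarized —
levels 5-7 are positive (1), levels 1-3 negative (0), and the neutral level
4 is excluded from training and evaluation. A 7-class variant is available
via ``scheme="likert"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support

from ._frames import frame_floor

__all__ = [
    "SMMModel",
    "F1Report",
    "binarize_likert",
    "frame_join",
    "train_smm",
    "predict_frames",
    "evaluate_f1",
]

#: columns of a sensor frame table that are not model features
META_COLUMNS = ("user_id", "frame_start", "likert", "label", "n_annotations")


def binarize_likert(likert) -> np.ndarray:
    """Map Likert 1-7 to binary mood class: >=5 -> 1, <=3 -> 0, 4 -> NaN (excluded)."""
    lik = np.asarray(likert, dtype=float)
    out = np.full(lik.shape, np.nan)
    out[lik >= 5] = 1.0
    out[lik <= 3] = 0.0
    return out


def frame_join(features: pd.DataFrame, annotations: pd.DataFrame,
               scheme: str = "binary") -> pd.DataFrame:
    """Attach ESM annotations to their enclosing 3-hour frames.

    Each annotation is assigned to the half-open frame [t, t+3h) containing
    its timestamp. Multiple annotations in one frame are averaged and the
    mean rounded half-to-even. Frames without an annotation are retained with
    NaN labels; annotations outside the feature table's time span are dropped
    with a warning.

    Returns the feature table plus columns ``likert`` (resolved level, NaN if
    none), ``n_annotations``, and ``label`` (per ``scheme``).
    """
    if scheme not in ("binary", "likert"):
        raise ValueError(f"unknown scheme {scheme!r}")
    feats = features.copy()
    feats["frame_start"] = pd.to_datetime(feats["frame_start"])

    if len(annotations):
        ann = annotations.copy()
        ann["frame_start"] = frame_floor(ann["timestamp"]).to_numpy()
        lo = feats["frame_start"].min()
        hi = feats["frame_start"].max()
        inside = (ann["frame_start"] >= lo) & (ann["frame_start"] <= hi)
        if (~inside).any():
            warnings.warn(
                f"dropped {(~inside).sum()} annotation(s) outside the feature period",
                stacklevel=2)
            ann = ann.loc[inside]
        grouped = ann.groupby(["user_id", "frame_start"])["likert"].agg(["mean", "size"])
        grouped.columns = ["likert", "n_annotations"]
        # mean of Likert levels rounded half-to-even, per the documented rule
        grouped["likert"] = np.rint(grouped["likert"])
        out = feats.merge(grouped.reset_index(), on=["user_id", "frame_start"], how="left")
    else:
        out = feats
        out["likert"] = np.nan
        out["n_annotations"] = 0

    out["n_annotations"] = out["n_annotations"].fillna(0).astype(int)
    out["label"] = binarize_likert(out["likert"]) if scheme == "binary" else out["likert"]
    return out


@dataclass
class SMMModel:
    """Fitted sensor mood model (one pooled model across all users)."""

    classifier: RandomForestClassifier
    feature_columns: list[str]
    scheme: str
    classes: np.ndarray
    n_train: int
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_frames(self, features)

    def predict_score(self, features: pd.DataFrame) -> np.ndarray:
        """Probability of the highest class (binary: P(positive))."""
        X = _feature_matrix(self, features)
        return self.classifier.predict_proba(X)[:, -1]


def _feature_matrix(model: SMMModel, features: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.feature_columns if c not in features.columns]
    extra = [c for c in features.columns
             if c not in model.feature_columns and c not in META_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing {missing}, unexpected {extra}")
    return features[model.feature_columns].to_numpy(dtype=float)


def train_smm(labeled_frames: pd.DataFrame, scheme: str = "binary", seed: int = 0,
              n_estimators: int = 200, min_samples_leaf: int = 5,
              class_weight: str | None = "balanced") -> SMMModel:
    """Train one pooled SMM on all labeled frames.

    ``labeled_frames`` is the output of :func:`frame_join`; rows with a NaN
    ``label`` are ignored. Class imbalance is handled with inverse-frequency
    class weights by default. Raises if no labels or only one class remain.
    """
    if "label" not in labeled_frames.columns:
        raise ValueError("labeled_frames must carry a 'label' column (run frame_join)")
    feature_cols = [c for c in labeled_frames.columns if c not in META_COLUMNS]
    if not feature_cols:
        raise ValueError("no feature columns found")

    mask = labeled_frames["label"].notna()
    if not mask.any():
        raise ValueError("no labels available: every frame is unlabeled")
    train = labeled_frames.loc[mask]
    X = train[feature_cols].to_numpy(dtype=float)
    y = train["label"].to_numpy()

    bad = [c for c, ok in zip(feature_cols, np.isfinite(X).all(axis=0)) if not ok]
    if bad:
        raise ValueError(f"non-finite values in feature column(s): {bad}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training labels contain a single class ({classes[0]!r}); "
                         "at least 2 classes are required")

    clf = RandomForestClassifier(
        n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
        class_weight=class_weight, random_state=seed, n_jobs=1,
    )
    clf.fit(X, y)
    return SMMModel(classifier=clf, feature_columns=feature_cols, scheme=scheme,
                    classes=classes, n_train=len(train), seed=seed)


def predict_frames(model: SMMModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted mood class for every input frame (row order preserved)."""
    X = _feature_matrix(model, features)
    if not np.isfinite(X).all():
        bad = [c for c, ok in zip(model.feature_columns, np.isfinite(X).all(axis=0))
               if not ok]
        raise ValueError(f"non-finite values in feature column(s): {bad}")
    return model.classifier.predict(X)


@dataclass
class F1Report:
    """Micro/macro F1 with per-class precision/recall.

    Macro-F1 is the unweighted mean of per-class F1 over the union of classes
    present in truth or predictions (a class never predicted and never true
    contributes 0 — the degenerate single-class case reports that class's F1).
    """

    micro_f1: float
    macro_f1: float
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def evaluate_f1(truth, predictions) -> F1Report:
    """Compute micro (global-count) and macro (unweighted class-mean) F1."""
    y_true = np.asarray(truth)
    y_pred = np.asarray(predictions)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: truth {y_true.shape} vs predictions {y_pred.shape}")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    p, r, f, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    per_class = pd.DataFrame(
        {"precision": p, "recall": r, "f1": f, "support": support},
        index=pd.Index(labels, name="class"))
    micro = float((y_true == y_pred).mean())  # accuracy == micro-F1 in single-label tasks
    macro = float(f.mean())
    return F1Report(micro_f1=micro, macro_f1=macro, per_class=per_class)
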