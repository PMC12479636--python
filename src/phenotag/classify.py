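"""39-class species-phenostage classification on image-derived feature vectors.

The real front end is a pre-trained CNN that maps each plant image to a
fixed-length deep-feature vector; a maximum-margin classifier (SVM) is then
trained on those vectors to separate all (species, stage) combinations.
This module covers the split / train / predict / evaluate cycle. The CNN
itself is abstracted behind :class:`FeatureExtractor`; shipped
implementations are an identity pass-through for precomputed vectors and a
toy color-histogram + moment extractor so the image -> feature -> class
path can be exercised end to end on rendered toy images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .scheme import PhenostageScheme, Stage

__all__ = [
    "LabeledFeatureSet",
    "PhenostageClassifier",
    "EvaluationReport",
    "stratified_split",
    "train_classifier",
    "predict",
    "evaluate",
    "f1_score",
    "FeatureExtractor",
    "IdentityExtractor",
    "ToyImageExtractor",
]


def class_label(species: str, stage: Stage | str) -> str:
    """Combined class label used internally: ``"<species>|<stage>"``."""
    return f"{species}|{Stage(stage).value}"


def split_label(label: str) -> tuple[str, Stage]:
    sp, st = label.rsplit("|", 1)
    return sp, Stage(st)


@dataclass
class LabeledFeatureSet:
    """Feature vectors with (species, stage) labels.

    All vectors share one length; every label must belong to the scheme if
    one is supplied at construction.
    """

    ids: np.ndarray
    X: np.ndarray
    species: np.ndarray
    stage: np.ndarray  # Stage values as str

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.X = np.asarray(self.X, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.stage = np.asarray(
            [Stage(s).value for s in np.asarray(self.stage).ravel()], dtype=object
        )
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, dim)")
        n = len(self.X)
        if not (len(self.ids) == len(self.species) == len(self.stage) == n):
            raise ValueError("ids, X, species, stage must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return np.array(
            [class_label(sp, st) for sp, st in zip(self.species, self.stage)],
            dtype=object,
        )

    def validate_against(self, scheme: PhenostageScheme) -> None:
        for sp, st in zip(self.species, self.stage):
            if not scheme.has_class(sp, st):
                raise ValueError(f"label not in scheme: ({sp!r}, {st!r})")

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            ids=self.ids[idx], X=self.X[idx],
            species=self.species[idx], stage=self.stage[idx],
        )


def stratified_split(
    data: LabeledFeatureSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Split into train/test preserving per-class proportions.

    Rounding rule: each class contributes ``floor(train_fraction * n_c)``
    records to train (at least 1, at most ``n_c - 1``); remaining train
    slots up to ``round(train_fraction * N)`` are then assigned one per
    class in a seeded random class order. Which records of a class land in
    train is decided by a seeded shuffle. Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If any class has fewer than 2 members (naming the class) or the
        fraction is outside (0, 1).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = data.labels
    classes, counts = np.unique(labels, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {c!r} has only {n} member(s); need >= 2 to split")

    n_train = {c: max(1, int(np.floor(train_fraction * n))) for c, n in zip(classes, counts)}
    n_by_class = dict(zip(classes, counts))
    for c in classes:  # keep at least one test record per class
        n_train[c] = min(n_train[c], n_by_class[c] - 1)
    target = int(round(train_fraction * len(data)))
    deficit = target - sum(n_train.values())
    order = rng.permutation(len(classes))
    for k in order:
        if deficit <= 0:
            break
        c = classes[k]
        if n_train[c] < n_by_class[c] - 1:
            n_train[c] += 1
            deficit -= 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        train_idx.extend(idx[: n_train[c]])
        test_idx.extend(idx[n_train[c]:])
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))
    return data.subset(train_idx), data.subset(test_idx)


@dataclass
class PhenostageClassifier:
    """A fitted multi-class maximum-margin classifier over scheme classes."""

    model: Pipeline
    classes_: np.ndarray
    dim: int
    params: dict = field(default_factory=dict)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[0] == 0:
            return np.array([], dtype=object)
        if X.shape[1] != self.dim:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[1]}, trained on {self.dim}"
            )
        return self.model.predict(X).astype(object)


def train_classifier(
    train: LabeledFeatureSet,
    kernel: str = "linear",
    C: float = 1.0,
    scale: bool = False,
    seed: int = 0,
) -> PhenostageClassifier:
    """Fit the multi-class SVM (one-vs-one voting) on a labeled feature set.

    Defaults: linear kernel, C=1, no feature scaling (deep-feature
    stand-ins are generated on a common scale); set ``scale=True`` to
    standardize features first. Deterministic for identical inputs.
    """
    labels = train.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least 2 classes")
    steps = []
    if scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel=kernel, C=C, decision_function_shape="ovo",
                             random_state=seed)))
    model = Pipeline(steps)
    model.fit(train.X, labels.astype(str))
    return PhenostageClassifier(
        model=model,
        classes_=model.named_steps["svm"].classes_,
        dim=train.dim,
        params={"kernel": kernel, "C": C, "scale": scale},
    )


def predict(clf: PhenostageClassifier, X: np.ndarray) -> np.ndarray:
    """Predict one ``"species|stage"`` label per row of ``X``."""
    return clf.predict_labels(X)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvaluationReport:
    """Confusion matrix plus overall accuracy and per-class P/R/F1.

    ``confusion[i, j]`` counts test records of true class ``labels[i]``
    predicted as ``labels[j]``; accuracy is trace/total. Per-class metrics
    are computed from the confusion matrix alone; a class that is never
    predicted gets precision 0 by convention.
    """

    labels: list[str]
    confusion: np.ndarray
    accuracy: float
    per_class: pd.DataFrame  # index: label; columns precision, recall, f1, support

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(clf: PhenostageClassifier, test: LabeledFeatureSet) -> EvaluationReport:
    """Evaluate on a held-out set; all metrics derive from the confusion matrix."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    y_true = test.labels.astype(str)
    y_pred = predict(clf, test.X).astype(str)
    labels = sorted(set(y_true) | set(y_pred))
    cm = _skm.confusion_matrix(y_true, y_pred, labels=labels)
    total = cm.sum()
    acc = float(np.trace(cm)) / total
    rows = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        support = cm[i, :].sum()
        pred_n = cm[:, i].sum()
        prec = float(tp / pred_n) if pred_n > 0 else 0.0
        rec = float(tp / support) if support > 0 else 0.0
        rows[lab] = {
            "precision": prec,
            "recall": rec,
            "f1": f1_score(prec, rec),
            "support": int(support),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return EvaluationReport(labels=labels, confusion=cm, accuracy=acc, per_class=per_class)


# ---------------------------------------------------------------------------
# Feature extraction front end


class FeatureExtractor(Protocol):
    """Maps images to fixed-length feature vectors (stands in for the CNN)."""

    def extract(self, images: Sequence[np.ndarray]) -> np.ndarray: ...


class IdentityExtractor:
    """Pass-through for precomputed feature vectors."""

    def extract(self, images: Sequence[np.ndarray]) -> np.ndarray:
        X = np.asarray(images, dtype=float)
        return X.reshape(len(X), -1)


class ToyImageExtractor:
    """Color histograms + simple shape moments of small RGB images.

    Not a deep network: a deliberately simple 30-dimensional descriptor
    (8 bins per channel plus per-channel mean/sd) sufficient to separate
    the programmatically rendered toy specimens used in examples.
    """

    bins: int = 8

    def extract(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = []
        for img in images:
            img = np.asarray(img, dtype=float)
            if img.ndim != 3 or img.shape[2] != 3:
                raise ValueError("expected an RGB image array (h, w, 3)")
            chans = []
            for c in range(3):
                h, _ = np.histogram(img[..., c], bins=self.bins, range=(0, 256))
                chans.append(h / img[..., c].size)
                chans.append([img[..., c].mean() / 255.0, img[..., c].std() / 255.0])
            feats.append(np.concatenate([np.ravel(c) for c in chans]))
        return np.asarray(feats)
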