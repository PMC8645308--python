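"""Binarized-judgment labeling and the RBF-SVM texture discriminant.

Features are z-scored with training-set statistics before the Gaussian
kernel; ``kernel_scale`` is the kernel width sigma in
``K(u, v) = exp(-||u - v||^2 / sigma^2)`` (the scikit-learn ``gamma`` is
``1 / sigma^2``).  Named hyperparameter presets carry the published values
for the four reported models; they are presets, not reproduction claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError

__all__ = [
    "SVMHyperparams",
    "PRESETS",
    "LabeledFeatureTable",
    "TrainedSVM",
    "CVResult",
    "binarize_judgments",
    "train_svm",
    "predict",
    "cross_validate",
    "tune_hyperparams",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SVMHyperparams:
    box_constraint: float  # misclassification penalty C
    kernel_scale: float  # Gaussian kernel width sigma

    def __post_init__(self):
        if self.box_constraint <= 0 or self.kernel_scale <= 0:
            raise ValidationError(
                "box_constraint and kernel_scale must be positive, got "
                f"({self.box_constraint}, {self.kernel_scale})"
            )

    @property
    def gamma(self) -> float:
        return 1.0 / self.kernel_scale**2


PRESETS = {
    "texturality_top6": SVMHyperparams(916.85, 0.0543),
    "similarity_top6": SVMHyperparams(0.0142, 0.0015),
    "texturality_moments": SVMHyperparams(351.74, 1.2965),
    "similarity_moments": SVMHyperparams(9.6800, 1.7189),
}


@dataclass
class LabeledFeatureTable:
    """Per-image features plus binary texture(1)/non-texture(0) labels."""

    image_ids: list
    X: np.ndarray  # (n_images, n_features)
    y: np.ndarray  # (n_images,) in {0, 1}
    feature_labels: tuple
    source_proportion: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D")
        n, d = self.X.shape
        if len(self.image_ids) != n or self.y.shape != (n,):
            raise ValidationError("rows of X, image_ids and y must align")
        if len(self.feature_labels) != d:
            raise ValidationError("feature_labels must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature table contains non-finite values")
        if not np.all(np.isin(self.y, [0, 1])):
            raise ValidationError("labels must be 0 or 1")

    def subset_features(self, labels: Sequence[str]) -> "LabeledFeatureTable":
        idx = []
        for lab in labels:
            if lab not in self.feature_labels:
                raise ValidationError(f"unknown feature label {lab!r}")
            idx.append(self.feature_labels.index(lab))
        return LabeledFeatureTable(
            image_ids=list(self.image_ids),
            X=self.X[:, idx],
            y=self.y.copy(),
            feature_labels=tuple(labels),
            source_proportion=self.source_proportion,
        )

    def take(self, rows) -> "LabeledFeatureTable":
        rows = np.asarray(rows)
        return LabeledFeatureTable(
            image_ids=[self.image_ids[i] for i in rows],
            X=self.X[rows],
            y=self.y[rows],
            feature_labels=self.feature_labels,
            source_proportion=(
                None
                if self.source_proportion is None
                else np.asarray(self.source_proportion)[rows]
            ),
        )


def binarize_judgments(
    image_ids: Sequence, proportions: Sequence[float], threshold: float = 0.5
):
    """Label proportions above ``threshold`` 1 and below 0.

    Images exactly at the threshold are excluded and their ids returned
    separately: ``(kept_ids, labels, excluded_ids)``.
    """
    props = np.asarray(proportions, dtype=float)
    if np.any((props < 0) | (props > 1)) or not np.all(np.isfinite(props)):
        raise ValidationError("proportions must lie in [0, 1]")
    if len(image_ids) != props.size:
        raise ValidationError("image_ids and proportions must align")
    kept_ids, labels, excluded = [], [], []
    for iid, p in zip(image_ids, props):
        if p == threshold:
            excluded.append(iid)
        else:
            kept_ids.append(iid)
            labels.append(1 if p > threshold else 0)
    return kept_ids, np.asarray(labels, dtype=int), excluded


@dataclass
class TrainedSVM:
    """A fitted discriminant: standardization + RBF support-vector expansion.

    ``decision(x) = sum_j dual_coef[j] * exp(-gamma ||z - sv_j||^2) + bias``
    with ``z`` the per-feature z-scored input; label 1 iff decision > 0.
    """

    feature_labels: tuple
    hyperparams: SVMHyperparams
    offset: np.ndarray  # standardization means
    scale: np.ndarray  # standardization s.d. (zero-variance columns -> 1)
    support_vectors: np.ndarray  # (n_sv, d), standardized coordinates
    dual_coef: np.ndarray  # (n_sv,)
    bias: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_labels):
            raise ValidationError(
                f"expected {len(self.feature_labels)} features "
                f"({', '.join(self.feature_labels)}), got {X.shape[1]}"
            )
        Z = (X - self.offset) / self.scale
        sq = (
            np.sum(Z * Z, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.hyperparams.gamma * np.clip(sq, 0.0, None))
        return K @ self.dual_coef + self.bias


def train_svm(table: LabeledFeatureTable, hyper: SVMHyperparams) -> TrainedSVM:
    """Fit the RBF SVM on z-scored features (training rows only)."""
    classes, counts = np.unique(table.y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training table must contain both classes")
    if np.any(counts < 2):
        raise ValidationError("need at least 2 rows per class")
    mu = table.X.mean(axis=0)
    sd = table.X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (table.X - mu) / sd
    svc = SVC(C=hyper.box_constraint, kernel="rbf", gamma=hyper.gamma)
    svc.fit(Z, table.y)
    assert list(svc.classes_) == [0, 1]
    return TrainedSVM(
        feature_labels=tuple(table.feature_labels),
        hyperparams=hyper,
        offset=mu,
        scale=sd,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
    )


def predict(model: TrainedSVM, features, feature_labels: Sequence[str] | None = None):
    """Predict labels and signed decision values.

    ``features`` may be an array whose columns follow the model's feature
    order, or a mapping / sequence of mappings label -> value.  Returns
    ``(labels, decision_values)``.
    """
    if isinstance(features, dict):
        features = [features]
    if len(features) > 0 and isinstance(features[0], dict):
        rows = []
        for f in features:
            row = []
            for lab in model.feature_labels:
                if lab not in f:
                    raise ValidationError(f"missing feature {lab!r}")
                row.append(f[lab])
            rows.append(row)
        X = np.asarray(rows, dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if feature_labels is not None and tuple(feature_labels) != tuple(
            model.feature_labels
        ):
            extra = set(feature_labels) - set(model.feature_labels)
            missing = set(model.feature_labels) - set(feature_labels)
            raise ValidationError(
                f"feature labels mismatch (missing: {sorted(missing)}, "
                f"unexpected: {sorted(extra)})"
            )
    dec = model.decision_function(X)
    return (dec > 0).astype(int), dec


@dataclass
class CVResult:
    mean_accuracy: float
    fold_accuracies: list
    fold_test_indices: list = field(default_factory=list)


def cross_validate(
    table: LabeledFeatureTable,
    hyper: SVMHyperparams,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation; standardization refit per fold."""
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    if table.X.shape[0] < folds:
        raise ValidationError("fewer rows than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, test_sets = [], []
    for train_idx, test_idx in skf.split(table.X, table.y):
        model = train_svm(table.take(train_idx), hyper)
        labels, _ = predict(model, table.X[test_idx])
        accs.append(float(np.mean(labels == table.y[test_idx])))
        test_sets.append(test_idx.tolist())
    return CVResult(
        mean_accuracy=float(np.mean(accs)),
        fold_accuracies=accs,
        fold_test_indices=test_sets,
    )


def tune_hyperparams(
    table: LabeledFeatureTable,
    grid: Sequence,
    folds: int = 10,
    seed: int = 0,
):
    """Exhaustive grid search by mean CV accuracy.

    ``grid`` holds ``SVMHyperparams`` or ``(C, sigma)`` pairs.  Ties prefer
    the smaller box constraint, then the larger kernel scale.  Returns
    ``(best_hyperparams, records)`` where each record is a dict with the full
    CV outcome for audit.
    """
    grid = [
        h if isinstance(h, SVMHyperparams) else SVMHyperparams(*h) for h in grid
    ]
    if not grid:
        raise ValidationError("hyperparameter grid is empty")
    records = []
    for h in grid:
        cv = cross_validate(table, h, folds=folds, seed=seed)
        records.append(
            {
                "box_constraint": h.box_constraint,
                "kernel_scale": h.kernel_scale,
                "mean_accuracy": cv.mean_accuracy,
                "fold_accuracies": cv.fold_accuracies,
            }
        )
    best = min(
        records,
        key=lambda r: (-r["mean_accuracy"], r["box_constraint"], -r["kernel_scale"]),
    )
    return SVMHyperparams(best["box_constraint"], best["kernel_scale"]), records


# --- persistence -------------------------------------------------------------


def save_model(model: TrainedSVM, path) -> None:
    """Write a model as JSON; floats survive the round trip bit-exactly."""
    payload = {
        "format": "texturality-svm-v1",
        "feature_labels": list(model.feature_labels),
        "hyperparams": {
            "box_constraint": model.hyperparams.box_constraint,
            "kernel_scale": model.hyperparams.kernel_scale,
        },
        "offset": model.offset.tolist(),
        "scale": model.scale.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "bias": model.bias,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> TrainedSVM:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "texturality-svm-v1":
        raise ValidationError(f"{path}: not a texturality SVM model file")
    return TrainedSVM(
        feature_labels=tuple(payload["feature_labels"]),
        hyperparams=SVMHyperparams(**payload["hyperparams"]),
        offset=np.asarray(payload["offset"], dtype=float),
        scale=np.asarray(payload["scale"], dtype=float),
        support_vectors=np.asarray(payload["support_vectors"], dtype=float),
        dual_coef=np.asarray(payload["dual_coef"], dtype=float),
        bias=float(payload["bias"]),
    )
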