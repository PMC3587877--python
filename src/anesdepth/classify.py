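"""Reference-class classification of epochs into the four anesthesia states.

The model is a Gaussian class-conditional (quadratic discriminant) rule on
z-scored feature columns: per class a mean vector and full covariance are
estimated (ridge-regularized against singularity), and epochs are assigned
to the maximum-posterior class. Quadratic discriminants are the minimal
generative family consistent with the discriminant-analysis lineage of the
commercial depth indices; the family is pluggable behind :func:`fit`.

Evaluation uses stratified k-fold cross-validation with per-fold
z-scoring (training-fold statistics only) and pools the held-out
predictions into one confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .core import AnesthesiaState
from .features import FeatureMatrix

#: Ridge added to class covariances (sklearn reg_param); keeps the rule
#: defined when a feature is constant within a class (e.g. BS% = 0 awake).
DEFAULT_REG = 1e-3


@dataclass
class ClassifierModel:
    """Fitted Gaussian class-conditional model on a named feature subset."""

    subset: list[str]
    norm_mean: np.ndarray
    norm_std: np.ndarray
    class_order: list[int]
    means: np.ndarray  # (n_classes, n_features) in normalized space
    covariances: np.ndarray  # (n_classes, n_features, n_features)
    priors: np.ndarray
    reg_param: float = DEFAULT_REG
    _qda: QuadraticDiscriminantAnalysis | None = field(default=None, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subset": self.subset,
                "norm_mean": self.norm_mean.tolist(),
                "norm_std": self.norm_std.tolist(),
                "class_order": self.class_order,
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "priors": self.priors.tolist(),
                "reg_param": self.reg_param,
            },
            indent=1,
        )


@dataclass
class ClassificationReport:
    """4×4 confusion matrix with per-class sensitivity/specificity."""

    confusion: np.ndarray  # rows = true class, cols = predicted
    class_order: list[int]

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        """Total accuracy in percent: 100 × trace / total."""
        return 100.0 * float(np.trace(self.confusion)) / self.n_total

    def _per_class(self) -> dict[str, tuple[float, float]]:
        out = {}
        cm = self.confusion
        total = cm.sum()
        for i, code in enumerate(self.class_order):
            tp = cm[i, i]
            fn = cm[i, :].sum() - tp
            fp = cm[:, i].sum() - tp
            tn = total - tp - fn - fp
            sens = tp / (tp + fn) if tp + fn else float("nan")
            spec = tn / (tn + fp) if tn + fp else float("nan")
            out[AnesthesiaState(code).name] = (float(sens), float(spec))
        return out

    @property
    def sensitivity(self) -> dict[str, float]:
        return {k: v[0] for k, v in self._per_class().items()}

    @property
    def specificity(self) -> dict[str, float]:
        return {k: v[1] for k, v in self._per_class().items()}

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "classes": [AnesthesiaState(c).name for c in self.class_order],
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n": self.n_total,
        }


def _zscore_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant columns pass through
    return mean, std


def fit(
    features: FeatureMatrix,
    subset: list[str] | None = None,
    reg_param: float = DEFAULT_REG,
) -> ClassifierModel:
    """Fit the Gaussian class-conditional model on a feature subset.

    All four anesthesia classes must be present. Deterministic: repeated
    calls on the same data give identical models.
    """
    subset = list(subset) if subset is not None else features.feature_names
    if not subset:
        raise ValueError("feature subset must be non-empty")
    fm = features.select(subset).drop_incomplete()
    present = set(int(v) for v in np.unique(fm.labels))
    missing = [s.name for s in AnesthesiaState if s.value not in present]
    if missing:
        raise ValueError(f"missing classes in training data: {missing}")

    x = fm.data.to_numpy(float)
    mean, std = _zscore_stats(x)
    xz = (x - mean) / std

    qda = QuadraticDiscriminantAnalysis(reg_param=reg_param, store_covariance=True)
    qda.fit(xz, fm.labels)
    return ClassifierModel(
        subset=subset,
        norm_mean=mean,
        norm_std=std,
        class_order=[int(c) for c in qda.classes_],
        means=np.asarray(qda.means_),
        covariances=np.asarray(qda.covariance_),
        priors=np.asarray(qda.priors_),
        reg_param=reg_param,
        _qda=qda,
    )


def predict(model: ClassifierModel, features: FeatureMatrix) -> np.ndarray:
    """Maximum-posterior class codes for each complete feature row.

    Sentinel-valued rows are excluded before prediction (their indices are
    simply absent from the training path; callers holding raw rows should
    call ``drop_incomplete`` themselves to keep labels aligned). Posterior
    ties break toward the shallower state (AWAKE < LIGHT < DEEP <
    ISOELECTRIC) through the fixed class order.
    """
    fm = features.select(model.subset).drop_incomplete()
    xz = (fm.data.to_numpy(float) - model.norm_mean) / model.norm_std
    if model._qda is None:
        raise ValueError("model was deserialized without its estimator; refit")
    return model._qda.predict(xz)


def evaluate(labels_true: np.ndarray, labels_pred: np.ndarray) -> ClassificationReport:
    """Confusion matrix and derived per-class metrics."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label lists must have equal length")
    if len(labels_true) == 0:
        raise ValueError("cannot evaluate empty label lists")
    order = [int(s) for s in AnesthesiaState]
    cm = confusion_matrix(labels_true, labels_pred, labels=order)
    return ClassificationReport(confusion=cm, class_order=order)


def cross_validated_report(
    features: FeatureMatrix,
    subset: list[str] | None = None,
    n_splits: int = 5,
    seed: int = 0,
    reg_param: float = DEFAULT_REG,
) -> ClassificationReport:
    """Stratified k-fold CV; held-out predictions pooled into one report.

    z-scoring statistics come from the training fold only, so no
    information leaks from the held-out epochs.
    """
    subset = list(subset) if subset is not None else features.feature_names
    fm = features.select(subset).drop_incomplete()
    x = fm.data.to_numpy(float)
    y = fm.labels

    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(x, y):
        mean, std = _zscore_stats(x[train_idx])
        qda = QuadraticDiscriminantAnalysis(reg_param=reg_param, store_covariance=False)
        qda.fit((x[train_idx] - mean) / std, y[train_idx])
        y_pred[test_idx] = qda.predict((x[test_idx] - mean) / std)
    return evaluate(y, y_pred)
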