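"""Classification of gaze trajectories: logistic feature model and Λ threshold.

Two classification rules are provided, both evaluated with stratified
k-fold cross-validation pooled over held-out folds:

* a logistic model p = 1 / (1 + exp(-L)) with L = β0 + Σ βj·zj on a small
  set of z-score-normalized trajectory features (by default mu_F, sigma_S
  and p_FS), fit by minimizing the unregularized negative log-likelihood;
* a single-threshold rule on the exploration metric Λ, with the cutoff
  chosen by exhaustive search over midpoints of the sorted training values
  to maximize training accuracy (ties break toward the lowest threshold),
  and the direction (whether high Λ means ASD) learned from the data.

ASD is the positive class throughout, which fixes the meaning of
sensitivity and precision.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .gaze_io import DataError

__all__ = [
    "POSITIVE_CLASS",
    "DEFAULT_LOGISTIC_FEATURES",
    "LogisticModel",
    "ThresholdClassifier",
    "ThresholdDirection",
    "CVConfig",
    "Grouping",
    "ConfusionMetrics",
    "fit_logistic",
    "predict_proba",
    "feature_importance_order",
    "fit_lambda_threshold",
    "cross_validate",
    "confusion_metrics",
    "LogisticClassifier",
    "LambdaThresholdClassifier",
]

POSITIVE_CLASS = "ASD"
NEGATIVE_CLASS = "TD"
DEFAULT_LOGISTIC_FEATURES = ("mu_F", "sigma_S", "p_FS")


# ---------------------------------------------------------------------------
# logistic model


@dataclass
class LogisticModel:
    """Fitted logistic rule on z-scored features.

    ``normalization`` maps each feature to its training (center, scale);
    the scale is the population standard deviation of the training column.
    ``separation_flagged`` is set when the optimizer hit its iteration cap,
    the signature of (quasi-)perfectly separable training data, in which
    case coefficients are large but capped rather than divergent.
    """

    beta0: float
    betas: dict[str, float]
    normalization: dict[str, tuple[float, float]]
    separation_flagged: bool = False

    def __post_init__(self) -> None:
        missing = set(self.betas) - set(self.normalization)
        if missing:
            raise DataError(f"features without a normalization entry: {sorted(missing)}")

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.betas if f not in features.columns]
        if missing:
            raise DataError(f"missing feature column(s): {missing}")
        L = np.full(len(features), self.beta0, dtype=float)
        for name, beta in self.betas.items():
            center, scale = self.normalization[name]
            L += beta * (features[name].to_numpy(float) - center) / scale
        return L


def fit_logistic(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    feature_names: tuple[str, ...] = DEFAULT_LOGISTIC_FEATURES,
    *,
    tol: float = 1e-8,
    max_iter: int = 5000,
    C: float = np.inf,
) -> LogisticModel:
    """Fit the logistic model by minimizing the negative log-likelihood.

    Features are z-scored using the training data only (center = mean,
    scale = population SD; a constant column gets scale 1).  Unregularized
    by default; pass a finite ``C`` for ridge-regularized fits on separable
    data.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present to fit a classifier")
    if len(features) < 4:
        raise DataError("at least 4 trials are required")

    X = features.loc[:, list(feature_names)].to_numpy(float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD (ddof=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale

    penalty = None if not np.isfinite(C) else "l2"
    clf = LogisticRegression(
        penalty=penalty,
        C=1.0 if penalty is None else C,
        tol=tol,
        max_iter=max_iter,
        solver="lbfgs",
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Z, y)
        hit_cap = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # on (quasi-)separable data the unregularized NLL tends to 0 and the MLE
    # diverges; the optimizer stops at capped coefficients, which we flag
    p_fit = np.clip(clf.predict_proba(Z)[:, 1], 1e-15, 1 - 1e-15)
    mean_nll = float(-np.mean(y * np.log(p_fit) + (1 - y) * np.log1p(-p_fit)))
    flagged = hit_cap or mean_nll < 1e-3

    return LogisticModel(
        beta0=float(clf.intercept_[0]),
        betas={name: float(b) for name, b in zip(feature_names, clf.coef_[0])},
        normalization={
            name: (float(c), float(s)) for name, c, s in zip(feature_names, center, scale)
        },
        separation_flagged=flagged,
    )


def predict_proba(model: LogisticModel, features: pd.DataFrame) -> np.ndarray:
    """p(ASD) = 1 / (1 + exp(-L)) per trial; class ASD iff p >= 0.5."""
    L = model.linear_predictor(features)
    return 1.0 / (1.0 + np.exp(-L))


def feature_importance_order(
    model: LogisticModel,
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    *,
    n_repeats: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank the model's features by |β| and by permutation importance.

    Permutation importance of a feature is the mean drop in accuracy over
    ``n_repeats`` random permutations of that single column.  Returns a
    frame indexed by feature with columns ``beta``, ``abs_beta``,
    ``rank_beta``, ``perm_importance``, ``rank_perm``.
    """
    y = _binary_labels(labels)
    rng = np.random.default_rng(seed)
    base_acc = float(np.mean((predict_proba(model, features) >= 0.5).astype(int) == y))

    rows = {}
    for name, beta in model.betas.items():
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            perm = features.copy()
            perm[name] = rng.permutation(perm[name].to_numpy())
            acc = float(np.mean((predict_proba(model, perm) >= 0.5).astype(int) == y))
            drops[r] = base_acc - acc
        rows[name] = {"beta": beta, "abs_beta": abs(beta), "perm_importance": float(drops.mean())}

    out = pd.DataFrame(rows).T
    out["rank_beta"] = out["abs_beta"].rank(ascending=False, method="min").astype(int)
    out["rank_perm"] = out["perm_importance"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank_beta")


# ---------------------------------------------------------------------------
# Λ threshold


class ThresholdDirection(str, enum.Enum):
    GREATER_IS_ASD = "greater_is_asd"
    LESS_IS_ASD = "less_is_asd"


@dataclass
class ThresholdClassifier:
    threshold: float
    direction: ThresholdDirection
    training_accuracy: float = float("nan")
    degenerate: bool = False  # all training Λ identical -> majority rule

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, float)
        if self.direction is ThresholdDirection.GREATER_IS_ASD:
            return (values >= self.threshold).astype(int)
        return (values < self.threshold).astype(int)


def fit_lambda_threshold(values: np.ndarray, labels: np.ndarray | pd.Series) -> ThresholdClassifier:
    """Exhaustive-search threshold on a scalar feature maximizing training accuracy.

    Candidate cuts are midpoints between consecutive distinct sorted values,
    plus sentinels below and above the data (the all-one-class rules).  Ties
    break toward the lowest threshold; the direction is chosen by training
    accuracy, preferring GREATER_IS_ASD on a tie so the rule is stable.
    """
    y = _binary_labels(labels)
    values = np.asarray(values, float)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")

    distinct = np.unique(values)
    if distinct.size == 1:
        majority = int(np.mean(y) >= 0.5)
        direction = (
            ThresholdDirection.GREATER_IS_ASD if majority == 1 else ThresholdDirection.LESS_IS_ASD
        )
        # threshold below every value => GREATER_IS_ASD predicts all ASD
        return ThresholdClassifier(
            threshold=float(distinct[0] - 1.0),
            direction=direction,
            training_accuracy=float(np.mean(y == majority)),
            degenerate=True,
        )

    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])

    best = None
    for direction in (ThresholdDirection.GREATER_IS_ASD, ThresholdDirection.LESS_IS_ASD):
        for thr in candidates:
            clf = ThresholdClassifier(threshold=float(thr), direction=direction)
            acc = float(np.mean(clf.predict(values) == y))
            key = (acc, direction is ThresholdDirection.GREATER_IS_ASD, -thr)
            if best is None or key > best[0]:
                best = (key, clf, acc)
    _, clf, acc = best
    clf.training_accuracy = acc
    return clf


# ---------------------------------------------------------------------------
# cross-validation and confusion metrics


class Grouping(str, enum.Enum):
    BY_TRIAL = "by_trial"
    BY_PARTICIPANT = "by_participant"


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    seed: int = 0
    grouping: Grouping = Grouping.BY_TRIAL

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise DataError("n_folds must be >= 2")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Pooled 2x2 confusion counts with the four standard ratios.

    Ratios with a zero denominator are NaN (undefined), never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion_metrics(predictions, truths) -> ConfusionMetrics:
    """Confusion counts with ASD as the positive class.

    Inputs may be string labels ("ASD"/"TD") or 0/1 integers (1 = ASD).
    """
    pred = _binary_labels(predictions)
    true = _binary_labels(truths)
    if pred.size != true.size:
        raise DataError(f"length mismatch: {pred.size} predictions vs {true.size} truths")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


class LogisticClassifier:
    """Fold-refittable wrapper around :func:`fit_logistic`."""

    def __init__(self, feature_names: tuple[str, ...] = DEFAULT_LOGISTIC_FEATURES, **fit_kwargs):
        self.feature_names = feature_names
        self.fit_kwargs = fit_kwargs
        self.model: LogisticModel | None = None

    def fit(self, features: pd.DataFrame, labels) -> "LogisticClassifier":
        self.model = fit_logistic(features, labels, self.feature_names, **self.fit_kwargs)
        return self

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return (predict_proba(self.model, features) >= 0.5).astype(int)


class LambdaThresholdClassifier:
    """Fold-refittable wrapper around :func:`fit_lambda_threshold`."""

    def __init__(self, column: str = "lambda"):
        self.column = column
        self.model: ThresholdClassifier | None = None

    def fit(self, features: pd.DataFrame, labels) -> "LambdaThresholdClassifier":
        self.model = fit_lambda_threshold(features[self.column].to_numpy(float), labels)
        return self

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(features[self.column].to_numpy(float))


def cross_validate(
    classifier,
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    cv: CVConfig = CVConfig(),
    *,
    groups: np.ndarray | None = None,
    max_redraws: int = 20,
) -> tuple[ConfusionMetrics, list[dict]]:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Each trial is predicted exactly once while held out; counts are pooled
    over folds before the ratio metrics are computed.  Under
    ``Grouping.BY_PARTICIPANT`` all trials of a participant share a fold
    (``groups`` must then be given).  If a fold's training part lacks one of
    the classes, folds are re-drawn with a derived seed (logged in the
    per-fold records).

    Returns ``(pooled_metrics, fold_records)``.
    """
    y = _binary_labels(labels)
    n = len(y)
    if n < cv.n_folds:
        raise DataError(f"need at least n_folds={cv.n_folds} trials, got {n}")
    if cv.grouping is Grouping.BY_PARTICIPANT and groups is None:
        raise DataError("BY_PARTICIPANT grouping requires a groups array")

    features = features.reset_index(drop=True)
    for attempt in range(max_redraws):
        seed = cv.seed + 1000003 * attempt
        if cv.grouping is Grouping.BY_PARTICIPANT:
            splitter = StratifiedGroupKFold(n_splits=cv.n_folds, shuffle=True, random_state=seed)
            splits = list(splitter.split(features, y, groups=groups))
        else:
            splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=seed)
            splits = list(splitter.split(features, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
    else:
        raise DataError("could not draw folds with both classes in every training set")

    predictions = np.full(n, -1, dtype=int)
    fold_records = []
    for fold_idx, (train, test) in enumerate(splits):
        classifier.fit(features.iloc[train], y[train])
        pred = np.asarray(classifier.predict(features.iloc[test]), dtype=int)
        predictions[test] = pred
        cm = confusion_metrics(pred, y[test])
        fold_records.append(
            {"fold": fold_idx, "n_test": int(len(test)), "seed_used": seed, **cm.as_dict()}
        )

    assert np.all(predictions >= 0), "every trial must be predicted exactly once"
    return confusion_metrics(predictions, y), fold_records


# ---------------------------------------------------------------------------
# helpers


def _binary_labels(labels) -> np.ndarray:
    """Coerce ASD/TD strings or 0/1 ints to an int array with ASD = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        out = np.empty(arr.size, dtype=int)
        for i, v in enumerate(arr.ravel()):
            s = str(v).strip().upper()
            if s == POSITIVE_CLASS:
                out[i] = 1
            elif s == NEGATIVE_CLASS:
                out[i] = 0
            else:
                raise DataError(f"unknown class label {v!r}; expected 'ASD' or 'TD'")
        return out
    out = arr.astype(int).ravel()
    if not np.all((out == 0) | (out == 1)):
        raise DataError("integer labels must be 0 (TD) or 1 (ASD)")
    return out


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan
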