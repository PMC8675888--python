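"""One-vs-rest IC classifiers with repeated-split validation and
balance-aware model selection.

Three fixed-hyperparameter model families are compared per IC class:
L2-regularized logistic regression (C=1.0, liblinear), a linear SVM
(C=1.0), and gradient-boosted trees (30 estimators, depth 4).  Validation
is a repeated stratified 70/30 train-test split (50 repeats by default),
reporting ROC-AUC, PR-AUC and F1 per split, plus mean curves with
pointwise 95% bands on a fixed 101-point grid.  No hyperparameters are
tuned.  The winning family per class is the one with the best mean ROC-AUC
when the class is relatively balanced, or the best mean PR-AUC when the
positive fraction falls below the balance threshold (PR-AUC reflects
performance on rare classes far better than ROC-AUC).

Linear models see standardized features (scaler fit on the training fold
only); trees take raw features.  SVM ranking scores are signed decision
margins, without probability calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (average_precision_score, f1_score,
                             precision_recall_curve, roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
import xgboost
from xgboost import XGBClassifier

from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "MODEL_FAMILIES",
    "TaskSpec",
    "ValidationReport",
    "TrainedModel",
    "ClassifierError",
    "repeated_split_validate",
    "select_model",
    "fit_final",
    "predict",
    "save_model",
    "load_model",
]

#: Fixed family order (also the final tie-break order).
MODEL_FAMILIES = ("logreg", "xgb", "svm")

_HYPERPARAMS = {
    # liblinear with the default L2 penalty
    "logreg": {"C": 1.0, "solver": "liblinear"},
    "svm": {"C": 1.0},
    "xgb": {"n_estimators": 30, "max_depth": 4},
}

_CURVE_GRID = np.linspace(0.0, 1.0, 101)


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: a class, the features, and the protocol."""

    class_name: str
    feature_names: tuple[str, ...] = FEATURE_NAMES
    families: tuple[str, ...] = MODEL_FAMILIES
    split_fraction: float = 0.7
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")


def _make_estimator(family: str, seed: int):
    if family == "logreg":
        return Pipeline([
            ("scale", StandardScaler()),
            ("model", LogisticRegression(random_state=seed,
                                         **_HYPERPARAMS["logreg"])),
        ])
    if family == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("model", LinearSVC(random_state=seed, **_HYPERPARAMS["svm"])),
        ])
    if family == "xgb":
        return XGBClassifier(random_state=seed, n_jobs=1,
                             eval_metric="logloss", **_HYPERPARAMS["xgb"])
    raise ClassifierError(f"unknown model family {family!r}")


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous ranking scores: probability of the positive class, or the
    signed margin for the SVM."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return estimator.decision_function(X)


def _coerce_features(features) -> pd.DataFrame:
    if isinstance(features, FeatureTable):
        return features.table
    return features


def _coerce_labels(labels, class_name: str) -> pd.Series:
    if hasattr(labels, "targets"):  # AggregatedLabels
        return labels.targets[class_name].astype(bool)
    if isinstance(labels, pd.DataFrame):
        return labels[class_name].astype(bool)
    return pd.Series(labels).astype(bool)


@dataclass
class ValidationReport:
    """Per-split metrics, aggregated curves and class balance info."""

    metrics: pd.DataFrame          # class, family, repeat, roc_auc, pr_auc, f1
    curves: dict = field(default_factory=dict)
    # (class, family) -> {"roc": {...}, "pr": {...}} with grid/mean/lo/hi
    positive_fraction: dict = field(default_factory=dict)
    n_repeats: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of each metric per class x family."""
        g = self.metrics.groupby(["class", "family"], sort=False)
        out = g[["roc_auc", "pr_auc", "f1"]].agg(["mean", "std"])
        out.columns = ["_".join(col) for col in out.columns]
        return out.reset_index()

    def merge(self, other: "ValidationReport") -> "ValidationReport":
        return ValidationReport(
            metrics=pd.concat([self.metrics, other.metrics],
                              ignore_index=True),
            curves={**self.curves, **other.curves},
            positive_fraction={**self.positive_fraction,
                               **other.positive_fraction},
            n_repeats=max(self.n_repeats, other.n_repeats),
        )


def _aggregate_curves(xs_list, ys_list, reverse: bool = False):
    interp = []
    for xs, ys in zip(xs_list, ys_list):
        if reverse:
            xs, ys = xs[::-1], ys[::-1]
        interp.append(np.interp(_CURVE_GRID, xs, ys))
    arr = np.vstack(interp)
    return {
        "grid": _CURVE_GRID.copy(),
        "mean": arr.mean(axis=0),
        "lo": np.percentile(arr, 2.5, axis=0),
        "hi": np.percentile(arr, 97.5, axis=0),
    }


def repeated_split_validate(features, labels, spec: TaskSpec
                            ) -> ValidationReport:
    """Repeated stratified 70/30 validation of every family in ``spec``.

    Components with missing features are dropped with their ids recorded
    nowhere else than the report's metrics index; the task errors if fewer
    than 10 components or fewer than 2 positives/negatives remain.
    """
    X_df = _coerce_features(features)[list(spec.feature_names)]
    y = _coerce_labels(labels, spec.class_name).reindex(X_df.index)
    keep = X_df.notna().all(axis=1) & y.notna()
    X_df, y = X_df[keep], y[keep].astype(bool)
    if len(X_df) < 10:
        raise ClassifierError(
            f"{spec.class_name}: needs >= 10 complete components, "
            f"got {len(X_df)}")
    n_pos = int(y.sum())
    if n_pos < 2 or len(y) - n_pos < 2:
        raise ClassifierError(
            f"{spec.class_name}: needs >= 2 positives and >= 2 negatives "
            f"(got {n_pos} of {len(y)})")
    X = X_df.to_numpy(dtype=float)
    yv = y.to_numpy()

    splitter = StratifiedShuffleSplit(n_splits=spec.n_repeats,
                                      train_size=spec.split_fraction,
                                      random_state=spec.seed)
    splits = list(splitter.split(X, yv))

    rows = []
    roc_pts = {f: ([], []) for f in spec.families}
    pr_pts = {f: ([], []) for f in spec.families}
    for repeat, (tr, te) in enumerate(splits):
        sub = 0
        while len(np.unique(yv[te])) < 2:  # stratification prevents this
            resampler = StratifiedShuffleSplit(
                n_splits=1, train_size=spec.split_fraction,
                random_state=spec.seed + 1_000_003 * (sub + 1))
            tr, te = next(resampler.split(X, yv))
            sub += 1
        for family in spec.families:
            est = _make_estimator(family, spec.seed)
            est.fit(X[tr], yv[tr])
            scores = _scores(est, X[te])
            y_pred = est.predict(X[te])
            rows.append({
                "class": spec.class_name, "family": family, "repeat": repeat,
                "roc_auc": roc_auc_score(yv[te], scores),
                "pr_auc": average_precision_score(yv[te], scores),
                "f1": f1_score(yv[te], y_pred),
            })
            fpr, tpr, _ = roc_curve(yv[te], scores)
            roc_pts[family][0].append(fpr)
            roc_pts[family][1].append(tpr)
            prec, rec, _ = precision_recall_curve(yv[te], scores)
            pr_pts[family][0].append(rec)
            pr_pts[family][1].append(prec)

    curves = {}
    for family in spec.families:
        curves[(spec.class_name, family)] = {
            "roc": _aggregate_curves(*roc_pts[family]),
            "pr": _aggregate_curves(*pr_pts[family], reverse=True),
        }
    metrics = pd.DataFrame(rows, columns=["class", "family", "repeat",
                                          "roc_auc", "pr_auc", "f1"])
    return ValidationReport(
        metrics=metrics, curves=curves,
        positive_fraction={spec.class_name: n_pos / len(yv)},
        n_repeats=spec.n_repeats)


def select_model(report: ValidationReport,
                 balance_threshold: float = 0.25) -> dict[str, str]:
    """Winning family per class.

    Classes with a positive fraction below ``balance_threshold`` are
    deemed unbalanced and judged on mean PR-AUC; balanced classes on mean
    ROC-AUC.  Ties break on the other metric, then on the fixed family
    order.
    """
    if report.metrics.empty:
        raise ClassifierError("empty validation report")
    summary = report.summary().set_index(["class", "family"])
    selection = {}
    for cls in report.metrics["class"].unique():
        frac = report.positive_fraction.get(cls)
        unbalanced = frac is not None and frac < balance_threshold
        primary, secondary = (("pr_auc_mean", "roc_auc_mean") if unbalanced
                              else ("roc_auc_mean", "pr_auc_mean"))
        candidates = []
        for rank, family in enumerate(MODEL_FAMILIES):
            if (cls, family) not in summary.index:
                continue
            row = summary.loc[(cls, family)]
            candidates.append((-row[primary], -row[secondary], rank, family))
        if not candidates:
            raise ClassifierError(f"no families validated for class {cls!r}")
        selection[cls] = min(candidates)[3]
    return selection


@dataclass
class TrainedModel:
    """A fitted family wrapped with its feature schema for safe prediction."""

    family: str
    class_name: str
    feature_names: tuple[str, ...]
    estimator: object
    hyperparameters: dict = field(default_factory=dict)

    def _validate(self, X_df: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X_df.columns]
        if missing:
            raise ClassifierError(
                f"{self.class_name}/{self.family}: input is missing feature "
                f"columns {missing}")
        return X_df[list(self.feature_names)].to_numpy(dtype=float)

    def scores(self, features) -> pd.Series:
        X_df = _coerce_features(features)
        X = self._validate(X_df)
        return pd.Series(_scores(self.estimator, X), index=X_df.index,
                         name=self.class_name)

    @property
    def default_threshold(self) -> float:
        return 0.0 if self.family == "svm" else 0.5


def fit_final(features, labels, class_name: str, family: str,
              feature_names=FEATURE_NAMES, seed: int = 0) -> TrainedModel:
    """Fit ``family`` on all complete components with fixed
    hyperparameters."""
    X_df = _coerce_features(features)[list(feature_names)]
    y = _coerce_labels(labels, class_name).reindex(X_df.index)
    keep = X_df.notna().all(axis=1) & y.notna()
    X_df, y = X_df[keep], y[keep].astype(bool)
    if int(y.sum()) < 2:
        raise ClassifierError(f"{class_name}: needs >= 2 positives to fit")
    est = _make_estimator(family, seed)
    est.fit(X_df.to_numpy(dtype=float), y.to_numpy())
    return TrainedModel(family=family, class_name=class_name,
                        feature_names=tuple(feature_names), estimator=est,
                        hyperparameters=dict(_HYPERPARAMS[family]))


@dataclass
class PredictionResult:
    scores: pd.DataFrame  # component x class, continuous
    flags: pd.DataFrame   # component x class, bool


def predict(models: dict[str, TrainedModel], features,
            threshold: float | None = None) -> PredictionResult:
    """Independent per-class scores and flags (strictly above threshold).

    ``threshold`` defaults to each model's natural decision point
    (probability 0.5, margin 0); classes are independent, so a component
    may carry several flags or none.
    """
    scores = {}
    flags = {}
    for cls, model in models.items():
        s = model.scores(features)
        thr = model.default_threshold if threshold is None else threshold
        scores[cls] = s
        flags[cls] = s > thr
    return PredictionResult(scores=pd.DataFrame(scores),
                            flags=pd.DataFrame(flags))


# ---------------------------------------------------------------------------
# model archive: self-describing JSON, no opaque pickles

def _export_estimator(model: TrainedModel) -> dict:
    est = model.estimator
    if model.family in ("logreg", "svm"):
        scaler = est.named_steps["scale"]
        clf = est.named_steps["model"]
        return {
            "scaler_mean": scaler.mean_.tolist(),
            "scaler_scale": scaler.scale_.tolist(),
            "coef": clf.coef_.tolist(),
            "intercept": clf.intercept_.tolist(),
            "classes": np.asarray(clf.classes_).astype(int).tolist(),
        }
    # xgboost: embed the booster's own JSON serialization
    booster = est.get_booster().save_raw(raw_format="json").decode("utf-8")
    return {"booster_json": booster}


class _BoosterEstimator:
    """Minimal predict surface around a bare xgboost Booster (used after
    re-importing an archive; the objective is binary:logistic, so raw
    predictions are positive-class probabilities)."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, X):
        p = self.booster.inplace_predict(np.asarray(X, dtype=float))
        return np.stack([1.0 - p, p], axis=1)

    def predict(self, X):
        return self.predict_proba(X)[:, 1] > 0.5


def _import_estimator(family: str, payload: dict, seed: int = 0):
    if family in ("logreg", "svm"):
        scaler = StandardScaler()
        scaler.mean_ = np.array(payload["scaler_mean"])
        scaler.scale_ = np.array(payload["scaler_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = scaler.mean_.size
        if family == "logreg":
            clf = LogisticRegression(random_state=seed, **_HYPERPARAMS["logreg"])
        else:
            clf = LinearSVC(random_state=seed, **_HYPERPARAMS["svm"])
        clf.coef_ = np.array(payload["coef"])
        clf.intercept_ = np.array(payload["intercept"])
        clf.classes_ = np.array(payload["classes"])
        clf.n_features_in_ = clf.coef_.shape[1]
        return Pipeline([("scale", scaler), ("model", clf)])
    booster = xgboost.Booster()
    booster.load_model(bytearray(payload["booster_json"], "utf-8"))
    return _BoosterEstimator(booster)


def save_model(model: TrainedModel, path) -> None:
    """Write a self-describing JSON archive (family, hyperparameters,
    feature schema, fitted parameters)."""
    archive = {
        "format": "eegic-model/1",
        "family": model.family,
        "class_name": model.class_name,
        "feature_names": list(model.feature_names),
        "hyperparameters": model.hyperparameters,
        "estimator": _export_estimator(model),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(archive, fh, indent=1)


def load_model(path) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        archive = json.load(fh)
    if archive.get("format") != "eegic-model/1":
        raise ClassifierError(f"{path}: not an eegic model archive")
    estimator = _import_estimator(archive["family"], archive["estimator"])
    return TrainedModel(
        family=archive["family"],
        class_name=archive["class_name"],
        feature_names=tuple(archive["feature_names"]),
        estimator=estimator,
        hyperparameters=archive.get("hyperparameters", {}),
    )
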