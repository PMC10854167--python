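"""Multiclass tissue-of-origin classifiers on a selected CpG panel.

Three algorithms share one interface: a random forest, a lasso, and an
elastic net. The penalized models are multinomial logistic regressions
with an elastic-net penalty; the regularization strength is chosen by
cross-validated deviance on the training set, and features are
standardized internally (coefficients are reported back on the original
beta scale). The lasso is the elastic net at mixing parameter 1.

Prediction emits a per-class probability for every sample — softmax for
the penalized models, the fraction of trees voting for each class for the
forest — and calls the class with the highest probability, breaking exact
ties toward the lexicographically first class name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .matrix import BetaMatrix, SampleLabels
from .selection import RFParams

__all__ = [
    "ENConfig",
    "ClassifierModel",
    "PredictionResult",
    "ModelIOError",
    "train_classifier",
    "predict",
    "save_model",
    "load_model",
]

_FORMAT = "methpanel-model"
_FORMAT_VERSION = (1, 0)


class ModelIOError(ValueError):
    """A model file is corrupted, truncated, or of an unsupported version."""


@dataclass(frozen=True)
class ENConfig:
    """Elastic-net settings.

    ``alpha_mix`` is the L1/L2 mixing parameter (1 = lasso, 0 = ridge);
    0.5 is the conventional midpoint default. ``lambda_grid`` is either
    "auto" (a log-spaced grid) or an explicit sequence of penalty
    strengths; cross-validation selects among them by multinomial
    deviance.
    """

    alpha_mix: float = 0.5
    lambda_grid: object = "auto"
    cv_folds: int = 5
    standardize: bool = True
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.alpha_mix <= 1):
            raise ValueError("alpha_mix must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class ClassifierModel:
    algorithm: str  # rf | lasso | en
    classes: list[str]
    probe_ids: list[str]
    estimator: object
    #: per-probe training means, used both for standardization and as the
    #: default imputation values for probes missing on another platform
    impute_means: pd.Series
    scale: pd.Series | None  # training SDs when standardized, else None
    metadata: dict = field(default_factory=dict)

    def coefficients(self) -> pd.DataFrame | None:
        """Per-class coefficients on the original beta scale (en/lasso)."""
        if self.algorithm == "rf":
            return None
        coef = self.estimator.coef_ / (
            self.scale.to_numpy() if self.scale is not None else 1.0)
        return pd.DataFrame(coef, index=self.classes, columns=self.probe_ids)


@dataclass(frozen=True)
class PredictionResult:
    """Per-sample class probabilities, argmax calls and call margins."""

    probabilities: pd.DataFrame  # samples x classes, rows sum to 1
    predicted: pd.Series
    #: gap between the top and second probability
    margin: pd.Series
    tie: pd.Series  # exact top-probability ties, resolved lexicographically

    def to_tsv(self, path) -> None:
        out = self.probabilities.copy()
        out.insert(0, "predicted_class", self.predicted)
        out.to_csv(path, sep="\t", index_label="sample_id")


def _design(bm: BetaMatrix) -> np.ndarray:
    x = bm.data.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix has missing values; run harmonize_to_panel "
                         "with an imputation policy first")
    return x


def train_classifier(bm: BetaMatrix, labels: SampleLabels,
                     algorithm: str = "en", cfg: ENConfig | None = None,
                     rf_params: RFParams | None = None) -> ClassifierModel:
    """Fit one classifier on a panel-restricted training matrix."""
    if algorithm not in ("rf", "lasso", "en"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    x = _design(bm)
    y = labels.for_samples(bm.sample_ids)
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValueError("training data has a single class")

    means = pd.Series(x.mean(axis=0), index=bm.probe_ids)
    meta = {"version": __version__, "n_train": len(y),
            "class_counts": pd.Series(y).value_counts().to_dict()}

    if algorithm == "rf":
        rf = rf_params or RFParams()
        est = RandomForestClassifier(
            n_estimators=rf.ntree, min_samples_leaf=rf.node_size,
            max_features=rf.max_features(x.shape[1]),
            random_state=rf.seed, n_jobs=1)
        est.fit(x, y)
        meta["rf_params"] = {"ntree": rf.ntree, "node_size": rf.node_size,
                             "seed": rf.seed}
        return ClassifierModel(algorithm, classes, bm.probe_ids, est,
                               means, None, meta)

    cfg = cfg or ENConfig()
    mix = 1.0 if algorithm == "lasso" else cfg.alpha_mix
    folds = cfg.cv_folds
    min_count = int(pd.Series(y).value_counts().min())
    if min_count < folds:
        warnings.warn(f"smallest class has {min_count} samples; reducing "
                      f"CV folds from {folds} to {max(2, min_count)}",
                      stacklevel=2)
        folds = max(2, min_count)
    if cfg.standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xs = (x - means.to_numpy()) / sd
        scale = pd.Series(sd, index=bm.probe_ids)
    else:
        xs = x
        scale = None
    cs = 10 if cfg.lambda_grid == "auto" else [
        1.0 / (len(y) * lam) for lam in cfg.lambda_grid]
    est = LogisticRegressionCV(
        Cs=cs, l1_ratios=[mix], solver="saga", scoring="neg_log_loss",
        use_legacy_attributes=False,
        cv=StratifiedKFold(folds, shuffle=True, random_state=cfg.seed),
        max_iter=cfg.max_iter, random_state=cfg.seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*max_iter.*")
        est.fit(xs, y)
    meta["en_config"] = {"alpha_mix": mix, "cv_folds": folds,
                         "seed": cfg.seed, "C_selected": float(est.C_),
                         "hyperparameters_defaulted": True}
    return ClassifierModel(algorithm, classes, bm.probe_ids, est,
                           means, scale, meta)


def predict(model: ClassifierModel, bm: BetaMatrix) -> PredictionResult:
    """Class probabilities and argmax calls for harmonized samples."""
    if bm.probe_ids != model.probe_ids:
        raise ValueError(
            "input probes do not match the model's training panel; run "
            "harmonize_to_panel(bm, model.probe_ids, impute='training_mean', "
            "impute_values=model.impute_means) first")
    x = _design(bm)
    if model.algorithm == "rf":
        # vote fractions: each tree casts one hard vote per sample
        est = model.estimator
        k = len(est.classes_)
        votes = np.zeros((x.shape[0], k))
        lookup = {c: i for i, c in enumerate(est.classes_)}
        for tree in est.estimators_:
            pred = est.classes_[tree.predict(x).astype(int)]
            for ci, c in enumerate(est.classes_):
                votes[pred == c, ci] += 1
        probs = votes / len(est.estimators_)
        cols = list(est.classes_)
    else:
        xs = x - model.impute_means.to_numpy()
        if model.scale is not None:
            xs = xs / model.scale.to_numpy()
        probs = model.estimator.predict_proba(xs)
        cols = list(model.estimator.classes_)
    df = pd.DataFrame(probs, index=bm.sample_ids, columns=cols)
    df = df[sorted(cols)]  # lexicographic class order
    arr = df.to_numpy()
    top = arr.argmax(axis=1)  # first (lexicographic) class wins ties
    n_top = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1)
    part = np.sort(arr, axis=1)
    margin = part[:, -1] - part[:, -2] if arr.shape[1] > 1 else part[:, -1]
    return PredictionResult(
        probabilities=df,
        predicted=pd.Series(np.array(df.columns)[top], index=df.index,
                            name="predicted_class"),
        margin=pd.Series(margin, index=df.index, name="margin"),
        tie=pd.Series(n_top > 1, index=df.index, name="tie"),
    )


def save_model(model: ClassifierModel, path) -> None:
    """Serialize a model to a single self-contained, versioned archive."""
    joblib.dump({
        "format": _FORMAT,
        "format_version": list(_FORMAT_VERSION),
        "algorithm": model.algorithm,
        "classes": model.classes,
        "probe_ids": model.probe_ids,
        "estimator": model.estimator,
        "impute_means": model.impute_means,
        "scale": model.scale,
        "metadata": model.metadata,
    }, path)


def load_model(path) -> ClassifierModel:
    try:
        blob = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(blob, dict) or blob.get("format") != _FORMAT:
        raise ModelIOError(f"{path} is not a {_FORMAT} file")
    version = blob.get("format_version")
    if not version:
        raise ModelIOError(f"{path} lacks a format version")
    if version[0] > _FORMAT_VERSION[0]:
        raise ModelIOError(
            f"{path} uses format major version {version[0]}; this build "
            f"supports up to {_FORMAT_VERSION[0]}")
    return ClassifierModel(
        algorithm=blob["algorithm"], classes=blob["classes"],
        probe_ids=blob["probe_ids"], estimator=blob["estimator"],
        impute_means=blob["impute_means"], scale=blob["scale"],
        metadata=blob["metadata"])
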