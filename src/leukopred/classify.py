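"""Classifier heads (elastic-net GLM, random forest, linear SVM) and metrics.

Each head is tuned by stratified K-fold cross-validation over its
hyperparameter grid with mean ROC AUC as the selection score, then refit
on the full training set.  Grids follow the study protocol: 14 mixing
values alpha in [0, 0.8] with penalty strength lambda in [0, 1] for the
elastic net, mtry in {1,2,3,4} for the forest, and 11 log-spaced C values
in [1e-4, 1] for the linear SVM.  The positive class is "obstructive";
AUC is computed from the Mann-Whitney definition with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .matrix import ExpressionMatrix

ALGORITHMS = ("glm_elastic_net", "random_forest", "svm_linear")


# ---------------------------------------------------------------------------
# Hyperparameter grids
# ---------------------------------------------------------------------------

def _default_alphas() -> tuple[float, ...]:
    return tuple(np.linspace(0.0, 0.8, 14))


def _default_lambdas() -> tuple[float, ...]:
    return tuple(np.linspace(0.0, 1.0, 21))


@dataclass(frozen=True)
class ElasticNetGrid:
    """Elastic-net mixing (alpha) and penalty strength (lambda) ladders."""

    alphas: tuple[float, ...] = field(default_factory=_default_alphas)
    lambdas: tuple[float, ...] = field(default_factory=_default_lambdas)

    def __post_init__(self) -> None:
        if not self.alphas or not self.lambdas:
            raise ValueError("elastic-net grid must be non-empty")
        if min(self.alphas) < 0 or max(self.alphas) > 1:
            raise ValueError("alpha values must lie in [0, 1]")
        if min(self.lambdas) < 0:
            raise ValueError("lambda values must be >= 0")


@dataclass(frozen=True)
class RandomForestGrid:
    """Candidate mtry values (features sampled per split) and forest sizes.

    ``cv_n_estimators`` lets CV scoring use a smaller forest than the
    final importance/prediction forest; None means use ``n_estimators``.
    """

    mtry: tuple[int, ...] = (1, 2, 3, 4)
    n_estimators: int = 200
    cv_n_estimators: int | None = None

    def __post_init__(self) -> None:
        if not self.mtry or min(self.mtry) < 1:
            raise ValueError("mtry grid must be non-empty positive integers")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.cv_n_estimators is not None and self.cv_n_estimators < 1:
            raise ValueError("cv_n_estimators must be >= 1")


@dataclass(frozen=True)
class SVMGrid:
    """Linear-SVM cost ladder (log-spaced by default)."""

    C: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.logspace(-4, 0, 11))
    )

    def __post_init__(self) -> None:
        if not self.C or min(self.C) <= 0:
            raise ValueError("C grid must be non-empty and positive")


def default_grid(algorithm: str):
    if algorithm == "glm_elastic_net":
        return ElasticNetGrid()
    if algorithm == "random_forest":
        return RandomForestGrid()
    if algorithm == "svm_linear":
        return SVMGrid()
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_auc(scores, labels) -> float:
    """AUC from the Mann-Whitney definition: P(score+ > score-) + P(=)/2."""
    scores = np.asarray(scores, float)
    y = encode_labels(labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Confusion matrix at a score threshold plus ranking/agreement metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    sensitivity: float
    specificity: float
    kappa: float
    f1: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    threshold: float = 0.5
    kappa_degenerate: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "auc": self.auc, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "kappa": self.kappa, "f1": self.f1,
            "threshold": self.threshold,
        }

    def summary(self) -> str:
        return (
            f"n={self.n}  AUC={self.auc:.3f}  sens={self.sensitivity:.3f}  "
            f"spec={self.specificity:.3f}  kappa={self.kappa:.3f}  F1={self.f1:.3f}  "
            f"(TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} @ {self.threshold})"
        )


def compute_report(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion matrix (score > threshold -> positive), AUC, kappa, F1, ROC."""
    scores = np.asarray(scores, float)
    y = encode_labels(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    degenerate = p_e >= 1.0
    kappa = 0.0 if degenerate else (p_o - p_e) / (1.0 - p_e)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return EvalReport(tp, fp, tn, fn, compute_auc(scores, y), sensitivity,
                      specificity, kappa, f1, fpr, tpr, threshold, degenerate)


def encode_labels(labels) -> np.ndarray:
    """Map labels to 0/1 with 'obstructive' (or truthy) as the positive class."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biuf":
        return arr.astype(int)
    return (arr == "obstructive").astype(int)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _lambda_to_C(lam: float, n: int) -> float:
    # glmnet penalises (lambda/1) * n-normalised loss; sklearn uses C = 1/(n*lambda)
    return 1.0 / (n * max(lam, 1e-8))


def _make_estimator(algorithm: str, params: dict, n: int, seed: int):
    if algorithm == "glm_elastic_net":
        return LogisticRegression(
            solver="saga", l1_ratio=params["alpha"],
            C=_lambda_to_C(params["lambda"], n), max_iter=5000, tol=1e-4,
            random_state=seed,
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], max_features=params["mtry"],
            random_state=seed,
        )
    if algorithm == "svm_linear":
        return SVC(kernel="linear", C=params["C"], random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _candidates(algorithm: str, grid, n_features: int) -> list[dict]:
    """Grid candidates ordered so the first CV-AUC maximum is the most
    regularized choice (larger lambda, then smaller alpha / mtry / C)."""
    if algorithm == "glm_elastic_net":
        return [
            {"alpha": a, "lambda": l}
            for l in sorted(grid.lambdas, reverse=True)
            for a in sorted(grid.alphas)
        ]
    if algorithm == "random_forest":
        mtry = sorted({min(m, n_features) for m in grid.mtry})
        return [{"mtry": m, "n_estimators": grid.n_estimators} for m in mtry]
    if algorithm == "svm_linear":
        return [{"C": c} for c in sorted(grid.C)]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _raw_scores(algorithm: str, est, X: np.ndarray) -> np.ndarray:
    if algorithm == "svm_linear":
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


@dataclass
class TrainedModel:
    """A CV-tuned head refit on the full training slice."""

    algorithm: str
    features: list[str]
    params: dict
    estimator: object
    cv_table: pd.DataFrame  # one row per candidate with mean CV AUC
    platt: LogisticRegression | None = None  # SVM score calibration

    def predict_scores(self, X) -> np.ndarray:
        """Positive-class score in [0, 1] for each sample (rows of X)."""
        Xm = _as_sample_matrix(X, self.features)
        raw = _raw_scores(self.algorithm, self.estimator, Xm)
        if self.algorithm == "svm_linear":
            return self.platt.predict_proba(raw[:, None])[:, 1]
        return raw


def _as_sample_matrix(X, features: Sequence[str]) -> np.ndarray:
    """samples x features array from an ExpressionMatrix or DataFrame."""
    if isinstance(X, ExpressionMatrix):
        df = X.data.T
    elif isinstance(X, pd.DataFrame):
        df = X
    else:
        return np.asarray(X, float)
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise KeyError(f"features missing from matrix: {missing}")
    return df[list(features)].to_numpy(float)


def train_model(X, labels, features: Sequence[str], algorithm: str,
                grid=None, folds: int = 7, seed: int = 0) -> TrainedModel:
    """CV-tune one head over its grid (mean fold AUC) and refit on all data."""
    features = list(features)
    if not features:
        raise ValueError("feature list must be non-empty")
    if grid is None:
        grid = default_grid(algorithm)
    Xm = _as_sample_matrix(X, features)
    y = encode_labels(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present in the training labels")
    if min(int(y.sum()), int(len(y) - y.sum())) < folds:
        raise ValueError(
            f"cv folds ({folds}) exceed the smallest class size "
            f"({min(int(y.sum()), int(len(y) - y.sum()))})"
        )
    cands = _candidates(algorithm, grid, Xm.shape[1])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xm, y))
    mean_aucs = []
    for params in cands:
        aucs = []
        for tr, te in splits:
            est = _make_estimator(algorithm, params, len(tr), seed)
            est.fit(Xm[tr], y[tr])
            aucs.append(compute_auc(_raw_scores(algorithm, est, Xm[te]), y[te]))
        mean_aucs.append(float(np.mean(aucs)))
    best = int(np.argmax(mean_aucs))  # first max = most regularized by ordering
    params = cands[best]
    est = _make_estimator(algorithm, params, len(y), seed)
    est.fit(Xm, y)
    platt = None
    if algorithm == "svm_linear":
        platt = LogisticRegression(C=1e6, max_iter=1000)
        platt.fit(est.decision_function(Xm)[:, None], y)
    cv_table = pd.DataFrame(cands)
    cv_table["mean_cv_auc"] = mean_aucs
    return TrainedModel(algorithm, features, params, est, cv_table, platt)


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    return model.predict_scores(X)


# ---------------------------------------------------------------------------
# Model/Results objects
# ---------------------------------------------------------------------------

@dataclass
class ClassifierResults:
    """Fitted head plus training diagnostics."""

    model: TrainedModel
    auc_cv: float      # mean CV AUC of the selected hyperparameters
    auc_resub: float   # resubstitution AUC after the full-training refit
    train_report: EvalReport

    def evaluate(self, X, labels, threshold: float = 0.5) -> EvalReport:
        return compute_report(self.model.predict_scores(X), labels, threshold)

    def predict_scores(self, X) -> np.ndarray:
        return self.model.predict_scores(X)

    def summary(self) -> str:
        p = ", ".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                      for k, v in self.model.params.items())
        return (
            f"{self.model.algorithm} on features {self.model.features}\n"
            f"  selected hyperparameters: {p}\n"
            f"  mean CV AUC: {self.auc_cv:.3f}   resubstitution AUC: {self.auc_resub:.3f}\n"
            f"  training {self.train_report.summary()}"
        )


class TranscriptClassifier:
    """Model object for one classifier head on a standardized matrix.

    Parameters
    ----------
    X
        Standardized ExpressionMatrix (genes x samples) or DataFrame
        (samples x genes).
    labels
        Group labels aligned with the samples ("obstructive" positive).
    features
        Gene ids used by the model.
    algorithm
        One of ``glm_elastic_net``, ``random_forest``, ``svm_linear``.
    """

    def __init__(self, X, labels, features: Sequence[str], algorithm: str,
                 grid=None, folds: int = 7, seed: int = 0) -> None:
        self.X = X
        self.labels = labels
        self.features = list(features)
        self.algorithm = algorithm
        self.grid = grid
        self.folds = folds
        self.seed = seed

    def fit(self) -> ClassifierResults:
        model = train_model(self.X, self.labels, self.features, self.algorithm,
                            self.grid, self.folds, self.seed)
        scores = model.predict_scores(self.X if not isinstance(self.X, ExpressionMatrix)
                                      else self.X)
        report = compute_report(scores, self.labels)
        best_auc = float(model.cv_table["mean_cv_auc"].max())
        return ClassifierResults(model, best_auc, report.auc, report)
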