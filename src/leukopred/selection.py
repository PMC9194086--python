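"""Stability-voting feature selection: an iterated GLM -> RF -> RF ladder.

Each iteration ranks all genes with a cross-validated elastic-net logistic
model and keeps the top 100, re-ranks those with a cross-validated random
forest and keeps the top 50, then ranks once more with a random forest and
keeps the top 5.  After 20 iterations (fold assignment and forest
bootstraps re-randomized each time), genes appearing in strictly more
than ``vote_threshold`` of the per-iteration top-5 lists become the final
features.  Importance is |coefficient| for the GLM head and Gini impurity
decrease for the forests; all tie-breaks are documented and deterministic
(larger absolute point-biserial correlation with the class, then gene id).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .classify import (ElasticNetGrid, RandomForestGrid, _lambda_to_C,
                       compute_auc, encode_labels)
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def _selection_glm_grid() -> ElasticNetGrid:
    """Coarse elastic-net ladder for the per-iteration ranking stage.

    The fine 14 x 21 grid is the model-construction protocol; the
    selection stage only needs a hyperparameter good enough to rank
    genes, so a caret-style coarse ladder (3 mixing values x 7
    log-spaced strengths) keeps the 20-iteration loop tractable.
    """
    return ElasticNetGrid(alphas=(0.0, 0.4, 0.8),
                          lambdas=tuple(np.logspace(-3, 0, 5)))


def _selection_rf_grid() -> RandomForestGrid:
    # importance from 100-tree forests; CV scoring with 15-tree forests
    return RandomForestGrid(n_estimators=100, cv_n_estimators=15)


@dataclass
class SelectionConfig:
    """Parameters of the stability-selection ladder (defaults = protocol)."""

    n_iterations: int = 20
    top_glm: int = 100
    top_rf_first: int = 50
    top_rf_final: int = 5
    vote_threshold: int = 10  # strict: selected iff votes > vote_threshold
    cv_folds: int = 7
    subsample_fraction: float = 0.5  # stratified per-iteration subsample (1.0 = full data)
    base_seed: int = 0
    glm_grid: ElasticNetGrid = field(default_factory=_selection_glm_grid)
    rf_grid: RandomForestGrid = field(default_factory=_selection_rf_grid)

    def validate(self, n_genes: int | None = None) -> None:
        if not (0 < self.top_rf_final <= self.top_rf_first <= self.top_glm):
            raise ValueError("need 0 < top_rf_final <= top_rf_first <= top_glm")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.vote_threshold < self.n_iterations:
            raise ValueError("vote_threshold must lie in [0, n_iterations)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if n_genes is not None and self.top_glm > n_genes:
            logger.warning(
                "top_glm (%d) exceeds the number of genes (%d); ladder truncates",
                self.top_glm, n_genes,
            )


def _as_frame(X) -> pd.DataFrame:
    """samples x genes DataFrame from an ExpressionMatrix or DataFrame."""
    if isinstance(X, ExpressionMatrix):
        return X.data.T
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("X must be an ExpressionMatrix or a samples-x-genes DataFrame")


def _check_classes(y: np.ndarray, folds: int) -> None:
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"stratified {folds}-fold CV infeasible with class sizes {n_pos}/{n_neg}"
        )


def _point_biserial(Xm: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|corr(gene, class)| per column; 0 for zero-variance genes."""
    xc = Xm - Xm.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.abs(np.nan_to_num(r))


def _ordered(gene_ids: np.ndarray, importance: np.ndarray, corr: np.ndarray) -> list[str]:
    # lexsort: last key is primary -> importance desc, then |corr| desc, then id asc
    order = np.lexsort((gene_ids, -corr, -importance))
    return list(gene_ids[order])


def glm_rank(X, labels, grid: ElasticNetGrid | None = None, folds: int = 7,
             seed: int = 0) -> list[str]:
    """Rank genes by |coefficient| of a CV-tuned elastic-net logistic model.

    The (alpha, lambda) pair with the best mean CV AUC is chosen (ties go
    to larger lambda, then smaller alpha) and the model is refit on the
    full slice; zero-coefficient genes fall after non-zero ones, ordered
    by absolute point-biserial correlation then gene id.
    """
    grid = grid or ElasticNetGrid()
    df = _as_frame(X)
    y = encode_labels(labels)
    _check_classes(y, folds)
    Xm = df.to_numpy(float)
    if (Xm.std(axis=0) == 0).all():
        raise ValueError("degenerate input: every gene is constant")
    gene_ids = np.asarray(df.columns)
    corr = _point_biserial(Xm, y)

    alphas = sorted(grid.alphas)
    lambdas = sorted(grid.lambdas, reverse=True)  # warm-start path: strong -> weak
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xm, y))
    aucs = np.zeros((len(alphas), len(lambdas)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for ai, alpha in enumerate(alphas):
            for tr, te in splits:
                clf = LogisticRegression(
                    solver="saga", l1_ratio=alpha, C=1.0,
                    warm_start=True, max_iter=150, tol=2e-3, random_state=seed,
                )
                for li, lam in enumerate(lambdas):
                    clf.set_params(C=_lambda_to_C(lam, len(tr)))
                    clf.fit(Xm[tr], y[tr])
                    aucs[ai, li] += compute_auc(clf.decision_function(Xm[te]), y[te])
    aucs /= len(splits)
    # preference order for ties: larger lambda first, then smaller alpha
    best_ai, best_li, best_auc = 0, 0, -np.inf
    for li in range(len(lambdas)):
        for ai in range(len(alphas)):
            if aucs[ai, li] > best_auc:
                best_ai, best_li, best_auc = ai, li, aucs[ai, li]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final = LogisticRegression(
            solver="saga", l1_ratio=alphas[best_ai],
            C=_lambda_to_C(lambdas[best_li], len(y)), max_iter=2000, tol=1e-4,
            random_state=seed,
        ).fit(Xm, y)
    return _ordered(gene_ids, np.abs(final.coef_[0]), corr)


def rf_rank(X, labels, candidates: Sequence[str] | None = None,
            grid: RandomForestGrid | None = None, folds: int = 7,
            seed: int = 0, mtry: int | None = None,
            return_mtry: bool = False):
    """Rank candidate genes by Gini importance of a CV-tuned random forest.

    mtry is chosen by mean CV AUC over the grid (ties to smaller mtry)
    unless given explicitly; the forest is then refit on the full slice.
    Ties in importance break by absolute point-biserial correlation then
    gene id.  Deterministic given seed.
    """
    grid = grid or RandomForestGrid()
    df = _as_frame(X)
    if candidates is not None:
        missing = [g for g in candidates if g not in df.columns]
        if missing:
            raise KeyError(f"candidate genes missing from matrix: {missing}")
        df = df[list(candidates)]
    y = encode_labels(labels)
    _check_classes(y, folds)
    Xm = df.to_numpy(float)
    gene_ids = np.asarray(df.columns)
    corr = _point_biserial(Xm, y)

    if mtry is None:
        cv_trees = grid.cv_n_estimators or grid.n_estimators
        mtry_values = sorted({min(m, Xm.shape[1]) for m in grid.mtry})
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(Xm, y))
        mean_aucs = []
        for m in mtry_values:
            aucs = []
            for tr, te in splits:
                rf = RandomForestClassifier(
                    n_estimators=cv_trees, max_features=m, random_state=seed
                ).fit(Xm[tr], y[tr])
                aucs.append(compute_auc(rf.predict_proba(Xm[te])[:, 1], y[te]))
            mean_aucs.append(float(np.mean(aucs)))
        mtry = mtry_values[int(np.argmax(mean_aucs))]  # first max = smallest mtry
    rf = RandomForestClassifier(
        n_estimators=grid.n_estimators, max_features=min(mtry, Xm.shape[1]),
        random_state=seed,
    ).fit(Xm, y)
    order = _ordered(gene_ids, rf.feature_importances_, corr)
    return (order, mtry) if return_mtry else order


def _subsample_indices(y: np.ndarray, fraction: float, folds: int, seed: int) -> np.ndarray:
    """Stratified per-iteration subsample; keeps >= folds samples per class."""
    if fraction >= 1.0:
        return np.arange(len(y))
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        size = min(len(idx), max(int(round(fraction * len(idx))), folds))
        keep.append(rng.choice(idx, size=size, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class SelectionResults:
    """Vote tallies, per-iteration audit trail, and the final feature set."""

    votes: pd.Series                  # per-gene vote count (0..n_iterations)
    iteration_lists: list[list[str]]  # top-final list of every iteration
    final_features: list[str]
    config: SelectionConfig

    def audit(self) -> dict:
        return {
            "iterations": [list(l) for l in self.iteration_lists],
            "votes": {g: int(v) for g, v in self.votes.items() if v > 0},
            "final_features": list(self.final_features),
            "vote_threshold": self.config.vote_threshold,
        }

    def summary(self) -> str:
        voted = self.votes[self.votes > 0].sort_values(ascending=False)
        lines = [
            f"Stability selection: {self.config.n_iterations} iterations, "
            f"ladder {self.config.top_glm} -> {self.config.top_rf_first} -> "
            f"{self.config.top_rf_final}, keep votes > {self.config.vote_threshold}",
            f"  genes with >=1 vote: {len(voted)}",
            f"  final features ({len(self.final_features)}): "
            + (", ".join(self.final_features) if self.final_features else "(none)"),
        ]
        for g, v in voted.head(10).items():
            lines.append(f"    {g}: {v}/{self.config.n_iterations}")
        return "\n".join(lines)


def run_selection(X, labels, config: SelectionConfig | None = None) -> SelectionResults:
    """Run the full voting ladder; deterministic given data and config."""
    config = config or SelectionConfig()
    df = _as_frame(X)
    config.validate(n_genes=df.shape[1])
    y = encode_labels(labels)
    _check_classes(y, config.cv_folds)
    iteration_lists: list[list[str]] = []
    for i in range(config.n_iterations):
        seed = config.base_seed + i
        sub = _subsample_indices(y, config.subsample_fraction, config.cv_folds, seed)
        df_i, y_i = df.iloc[sub], y[sub]
        order = glm_rank(df_i, y_i, config.glm_grid, config.cv_folds, seed)
        survivors = order[: config.top_glm]
        order, mtry = rf_rank(df_i, y_i, survivors, config.rf_grid, config.cv_folds,
                              seed, return_mtry=True)
        survivors = order[: config.top_rf_first]
        # second forest pass reuses the CV-chosen mtry (fresh bootstraps)
        order = rf_rank(df_i, y_i, survivors, config.rf_grid, config.cv_folds,
                        seed + 1_000_000, mtry=mtry)
        iteration_lists.append(order[: config.top_rf_final])
    votes = pd.Series(0, index=df.columns, dtype=int, name="votes")
    for lst in iteration_lists:
        votes[lst] += 1
    selected = votes[votes > config.vote_threshold]
    final = list(selected.sort_values(ascending=False, kind="stable").index)
    final.sort(key=lambda g: (-votes[g], g))
    return SelectionResults(votes, iteration_lists, final, config)


class StabilitySelection:
    """Model object: stability-voting selection on a standardized matrix."""

    def __init__(self, X, labels, config: SelectionConfig | None = None) -> None:
        self.X = X
        self.labels = labels
        self.config = config or SelectionConfig()

    def fit(self) -> SelectionResults:
        return run_selection(self.X, self.labels, self.config)
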