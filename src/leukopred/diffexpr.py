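"""Covariate-adjusted differential expression with Holm correction.

Each gene is tested with a Gaussian linear model on the log2(x+1) scale,

    expression ~ intercept + group + z(log(age_days + 1)),

where the group coefficient is the log2 fold change (obstructive minus
non-obstructive) adjusted for the age confounding that dominates this
cohort, and its two-sided Wald p-value is Holm-corrected across genes.
A gene is called differentially expressed when |log2FC| >= fc_threshold
(default 1) and the Holm-adjusted p is < alpha (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, TransformStateError

logger = logging.getLogger(__name__)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    adjusted_(i) = min(1, max_{j<=i} (m-j+1) * p_(j)) over the ascending
    sort order; monotone in the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("all p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(factors * p[order]))
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def _design(group: np.ndarray, age_days: np.ndarray) -> tuple[np.ndarray, bool]:
    """Build [1, group, z(log(age+1))]; drops a constant age column."""
    n = len(group)
    log_age = np.log(np.asarray(age_days, float) + 1.0)
    sd = log_age.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0:
        logger.warning("age covariate is constant; dropping it from the design")
        return np.column_stack([np.ones(n), group]), False
    z = (log_age - log_age.mean()) / sd
    return np.column_stack([np.ones(n), group, z]), True


def _fit_genes(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS Wald test of the group coefficient for each row of Y."""
    n, p = X.shape
    if n - p <= 0:
        raise ValueError(f"zero residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - beta @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    coef = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p_raw = 2.0 * stats.t.sf(np.abs(t), dof)
    # zero residual variance: p is 1 for a zero effect, else effectively 0
    exact = se == 0.0
    p_raw[exact] = np.where(coef[exact] == 0.0, 1.0, np.finfo(float).tiny)
    return coef, np.clip(p_raw, np.finfo(float).tiny, 1.0)


def test_gene(values, group_labels, age_days) -> tuple[float, float]:
    """Single-gene covariate-adjusted test; returns (log2fc, raw p).

    ``group_labels`` may be 0/1 (1 = obstructive) or the group strings.
    """
    values = np.asarray(values, float)
    group = _encode_groups(group_labels)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    X, _ = _design(group, age_days)
    coef, p = _fit_genes(values[None, :], X)
    return float(coef[0]), float(p[0])


def _encode_groups(group_labels) -> np.ndarray:
    arr = np.asarray(group_labels)
    if arr.dtype.kind in "biuf":
        return arr.astype(float)
    return (arr == "obstructive").astype(float)


@dataclass
class DifferentialExpressionResults:
    """Per-gene effects, raw/Holm p-values and up/down/ns calls."""

    table: pd.DataFrame
    fc_threshold: float
    alpha: float

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["status"] != "ns"]

    def counts(self) -> pd.DataFrame:
        """Up/down DEG counts per biotype."""
        deg = self.degs
        out = (
            deg.groupby(["biotype", "status"], observed=True).size().unstack(fill_value=0)
            if len(deg)
            else pd.DataFrame()
        )
        return out

    def summary(self) -> str:
        deg = self.degs
        lines = [
            "Differential expression (group effect adjusted for log-age)",
            f"  genes tested : {len(self.table)}",
            f"  DEG rule     : |log2FC| >= {self.fc_threshold} and Holm p < {self.alpha}",
            f"  DEGs         : {len(deg)} ({(deg['status'] == 'up').sum()} up, "
            f"{(deg['status'] == 'down').sum()} down)",
        ]
        for biotype, sub in deg.groupby("biotype", observed=True):
            lines.append(f"    {biotype:7s}: {(sub['status'] == 'up').sum()} up, "
                         f"{(sub['status'] == 'down').sum()} down")
        return "\n".join(lines)


class DifferentialExpression:
    """Model object: covariate-adjusted per-gene tests over a log matrix.

    Parameters
    ----------
    matrix
        ExpressionMatrix in ``log`` state.
    metadata
        Sample metadata with ``sample_id``, ``group`` and ``age_days``.
    fc_threshold, alpha
        DEG decision thresholds (|log2FC| and Holm-adjusted p).
    """

    def __init__(self, matrix: ExpressionMatrix, metadata: pd.DataFrame,
                 fc_threshold: float = 1.0, alpha: float = 0.05) -> None:
        if matrix.transform_state != "log":
            raise TransformStateError(
                f"differential expression requires a log matrix, got {matrix.transform_state!r}"
            )
        if set(matrix.sample_ids) != set(metadata["sample_id"]):
            raise ValueError("matrix and metadata sample ids do not match")
        self.matrix = matrix
        self.metadata = metadata.set_index("sample_id").loc[matrix.sample_ids].reset_index()
        self.fc_threshold = fc_threshold
        self.alpha = alpha

    def fit(self) -> DifferentialExpressionResults:
        group = _encode_groups(self.metadata["group"].to_numpy())
        if group.sum() == 0 or group.sum() == len(group):
            raise ValueError("both groups must be present")
        X, _ = _design(group, self.metadata["age_days"].to_numpy())
        Y = self.matrix.data.to_numpy()
        coef, p_raw = _fit_genes(Y, X)
        p_adj = holm_adjust(p_raw)
        status = np.full(len(coef), "ns", dtype=object)
        sig = p_adj < self.alpha
        status[sig & (coef >= self.fc_threshold)] = "up"
        status[sig & (coef <= -self.fc_threshold)] = "down"
        table = pd.DataFrame(
            {
                "gene_id": self.matrix.gene_ids,
                "biotype": self.matrix.biotypes.to_numpy(),
                "log2fc": coef,
                "p_raw": p_raw,
                "p_holm": p_adj,
                "status": status,
            }
        )
        return DifferentialExpressionResults(table, self.fc_threshold, self.alpha)


def call_degs(matrix: ExpressionMatrix, metadata: pd.DataFrame,
              fc_threshold: float = 1.0, alpha: float = 0.05) -> DifferentialExpressionResults:
    """Functional wrapper around :class:`DifferentialExpression`."""
    return DifferentialExpression(matrix, metadata, fc_threshold, alpha).fit()
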