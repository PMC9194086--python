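"""Train/validation split rule and Table-1 style clinical group comparisons.

The split rule mirrors the study design: obstructive patients whose
obstruction could NOT be identified by echocardiography/CTA form the
training positives (the clinically hard cases), while identifiable
obstructive patients are held out for validation; non-obstructive
patients are ranked by surgical age and the oldest go to training.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import validate_metadata

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "obstructive"


def split_cohort(metadata: pd.DataFrame, n_non_validation: int) -> pd.Series:
    """Assign each sample to ``train`` or ``validation``.

    Obstructive & not imaging-identifiable -> train; obstructive &
    identifiable -> validation.  Non-obstructive samples are sorted by
    age descending (ties broken by ascending sample_id): the oldest go
    to train, the youngest ``n_non_validation`` to validation.
    """
    validate_metadata(metadata)
    non = metadata[metadata["group"] == "non_obstructive"]
    if not 0 <= n_non_validation <= len(non):
        raise ValueError(
            f"n_non_validation must be in [0, {len(non)}], got {n_non_validation}"
        )
    assignment = pd.Series("train", index=metadata["sample_id"], name="split")
    obs = metadata[metadata["group"] == "obstructive"]
    assignment[obs.loc[obs["imaging_identifiable"], "sample_id"]] = "validation"
    ranked = non.sort_values(["age_days", "sample_id"], ascending=[False, True])
    if n_non_validation:
        assignment[ranked["sample_id"].iloc[len(non) - n_non_validation:]] = "validation"
    return assignment


_EXACT_ENUM_LIMIT = 50_000  # exhaustive label permutations when feasible


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon Mann-Whitney U test.  Returns (U, p).

    Small samples (<= 50k distinct group assignments) use exhaustive
    permutation enumeration (tie-safe and exact); larger ones use the
    normal approximation with tie and continuity correction, the standard
    choice at the cohort sizes this pipeline targets.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    from math import comb
    if comb(len(x) + len(y), len(x)) <= _EXACT_ENUM_LIMIT:
        method = stats.PermutationMethod(n_resamples=_EXACT_ENUM_LIMIT)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _check_2x2(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("test undefined: a table margin is zero")
    return table


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = _check_2x2(table)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    table = _check_2x2(table)
    return float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])


def choose_categorical_test(table) -> str:
    """Fisher when any expected cell count is < 5, else Pearson chi-square."""
    table = _check_2x2(table)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return "fisher" if (expected < 5).any() else "pearson"


def cohort_table(
    metadata: pd.DataFrame,
    continuous: Sequence[str] = ("age_days", "weight_kg"),
    categorical: Sequence[str] = ("imaging_identifiable",),
) -> pd.DataFrame:
    """Table-1 style group comparison of clinical variables.

    Continuous variables: median (Q1, Q3) per group and a Wilcoxon p.
    Categorical (binary) variables: n (%) per group, with Fisher's exact
    test when any expected cell is < 5 and Pearson chi-square otherwise.
    Percentages are rounded to one decimal.
    """
    validate_metadata(metadata)
    for var in list(continuous) + list(categorical):
        if var not in metadata.columns:
            raise KeyError(f"unknown variable: {var!r}")
    obs = metadata[metadata["group"] == "obstructive"]
    non = metadata[metadata["group"] == "non_obstructive"]
    rows = []
    for var in continuous:
        xo, xn = obs[var].to_numpy(float), non[var].to_numpy(float)
        _, p = wilcoxon_rank_sum(xo, xn)
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "obstructive": "%.1f (%.1f, %.1f)"
                % (np.median(xo), np.percentile(xo, 25), np.percentile(xo, 75)),
                "non_obstructive": "%.1f (%.1f, %.1f)"
                % (np.median(xn), np.percentile(xn, 25), np.percentile(xn, 75)),
                "test": "wilcoxon",
                "p": p,
            }
        )
    for var in categorical:
        a, b = int(obs[var].astype(bool).sum()), int(non[var].astype(bool).sum())
        table = np.array([[a, len(obs) - a], [b, len(non) - b]])
        pct_o = round(100.0 * a / len(obs), 1) if len(obs) else 0.0
        pct_n = round(100.0 * b / len(non), 1) if len(non) else 0.0
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            test, p = "skipped", float("nan")
            logger.info("cohort_table: test skipped for %r (degenerate margin)", var)
        else:
            test = choose_categorical_test(table)
            p = fisher_exact_2x2(table) if test == "fisher" else pearson_chi2_2x2(table)[1]
        rows.append(
            {
                "variable": var,
                "kind": "categorical",
                "obstructive": f"{a} ({pct_o})",
                "non_obstructive": f"{b} ({pct_n})",
                "test": test,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
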