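"""Simulation-calibration benchmarks for the full pipeline.

Because the real cohort cannot be bundled, the pipeline's statistical
behaviour is validated by simulation: type-I control of the DEG rule and
emptiness of the stability-selection set under a null generator, recovery
of planted markers and validation AUC of the classifier heads under a
planted-signal generator, and bit-reproducibility of a full run.  These
routines are used by the test suite and the reproduction script; they are
also the recommended way to sanity-check the pipeline after changes.
"""

from __future__ import annotations

import json
import warnings

from .classify import ALGORITHMS, TranscriptClassifier
from .cohort import split_cohort
from .diffexpr import call_degs
from .matrix import apply_scaler, fit_scaler, log_transform
from .pipeline import run_pipeline
from .selection import SelectionConfig, run_selection
from .synthetic import SynthCohort, SynthConfig, simulate_cohort, truth_recovery_report

_MOD = 2**31 - 1


def _seed(base: int, offset: int) -> int:
    return int((base + offset) % _MOD)


def _standardized_train(cohort: SynthCohort, n_non_validation: int = 6):
    """Split, log-transform, scale on train; return (z_train, y_train, z_valid, y_valid)."""
    split = split_cohort(cohort.metadata, n_non_validation)
    logm = log_transform(cohort.matrix)
    train = [s for s in logm.sample_ids if split[s] == "train"]
    valid = [s for s in logm.sample_ids if split[s] == "validation"]
    z = apply_scaler(logm, fit_scaler(logm, train))
    meta = cohort.metadata.set_index("sample_id")
    return (
        z.subset_samples(train),
        meta.loc[train, "group"].to_numpy(),
        z.subset_samples(valid),
        meta.loc[valid, "group"].to_numpy(),
    )


def null_config(n_genes: int = 500, seed: int = 0) -> SynthConfig:
    """Study-shaped cohort with no planted signal."""
    return SynthConfig(n_genes=n_genes, n_planted_up=0, n_planted_down=0, seed=seed)


def planted_config(n_noise: int = 200, planted_log2fc: float = 3.0,
                   seed: int = 0) -> SynthConfig:
    """Study-shaped cohort with one up- and one down-regulated marker."""
    return SynthConfig(n_genes=n_noise + 2, n_planted_up=1, n_planted_down=1,
                       planted_log2fc=planted_log2fc, seed=seed)


def deg_null_false_call_rate(n_seeds: int = 100, n_genes: int = 500,
                             seed: int = 0) -> tuple[float, int]:
    """Fraction of genes called DEG across null cohorts (expect ~0)."""
    called = total = 0
    for i in range(n_seeds):
        cohort = simulate_cohort(null_config(n_genes, _seed(seed, i)))
        res = call_degs(log_transform(cohort.matrix), cohort.metadata)
        called += int((res.table["status"] != "ns").sum())
        total += len(res.table)
    return called / total, total


def selection_null_empty_fraction(n_runs: int = 10, n_genes: int = 500,
                                  seed: int = 0) -> tuple[float, int]:
    """Fraction of null cohorts on which the final feature set is empty."""
    empty = 0
    for i in range(n_runs):
        cohort = simulate_cohort(null_config(n_genes, _seed(seed, i)))
        z_train, y_train, _, _ = _standardized_train(cohort)
        res = run_selection(z_train, y_train,
                            SelectionConfig(base_seed=_seed(seed, 10_000 + i)))
        empty += not res.final_features
    return empty / n_runs, n_runs


def planted_recovery_rate(n_reps: int = 20, n_noise: int = 200,
                          planted_log2fc: float = 3.0,
                          seed: int = 0) -> tuple[float, int]:
    """Fraction of planted cohorts on which the final set contains both markers."""
    recovered = 0
    for i in range(n_reps):
        cohort = simulate_cohort(planted_config(n_noise, planted_log2fc, _seed(seed, i)))
        z_train, y_train, _, _ = _standardized_train(cohort)
        res = run_selection(z_train, y_train,
                            SelectionConfig(base_seed=_seed(seed, 20_000 + i)))
        report = truth_recovery_report(res.final_features, cohort.truth)
        recovered += report["recall"] == 1.0
    return recovered / n_reps, n_reps


def head_validation_auc_rates(n_seeds: int = 20, n_noise: int = 200,
                              planted_log2fc: float = 3.0, auc_threshold: float = 0.9,
                              seed: int = 0) -> dict[str, tuple[float, int]]:
    """Per-algorithm fraction of seeds with validation AUC >= threshold when
    trained on the two planted markers."""
    passes = {algo: 0 for algo in ALGORITHMS}
    for i in range(n_seeds):
        cohort = simulate_cohort(planted_config(n_noise, planted_log2fc, _seed(seed, i)))
        z_train, y_train, z_valid, y_valid = _standardized_train(cohort)
        features = list(cohort.truth["gene_id"])
        for algo in ALGORITHMS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = TranscriptClassifier(z_train, y_train, features, algo,
                                           seed=_seed(seed, 30_000 + i)).fit()
                auc = res.evaluate(z_valid, y_valid).auc
            passes[algo] += auc >= auc_threshold
    return {algo: (n / n_seeds, n_seeds) for algo, n in passes.items()}


def pipeline_reproducibility(seed: int = 0, n_genes: int = 150) -> bool:
    """Two identically seeded full pipeline runs serialize identically."""
    cohort = simulate_cohort(SynthConfig(n_genes=n_genes, seed=_seed(seed, 0)))
    cfg = SelectionConfig(n_iterations=6, vote_threshold=2, base_seed=_seed(seed, 1))
    def one():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_pipeline(cohort.matrix, cohort.metadata,
                                  selection_config=cfg, seed=_seed(seed, 1))
        return json.dumps(result.to_dict(), sort_keys=True)
    return one() == one()
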