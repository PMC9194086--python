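"""End-to-end pipeline: split -> transform -> DE -> selection -> heads.

One call chains every stage with a single base seed so a full analysis is
bit-reproducible; the returned result serializes to a JSON-stable dict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .classify import ALGORITHMS, EvalReport, TranscriptClassifier
from .cohort import split_cohort
from .diffexpr import DifferentialExpression, DifferentialExpressionResults
from .matrix import ExpressionMatrix, apply_scaler, fit_scaler, log_transform
from .selection import SelectionConfig, SelectionResults, StabilitySelection


@dataclass
class PipelineResult:
    split: pd.Series
    de: DifferentialExpressionResults | None
    selection: SelectionResults | None
    features: list[str]
    heads: dict  # algorithm -> {"params", "train": EvalReport, "validation": EvalReport}

    def to_dict(self) -> dict:
        out: dict = {
            "split": {s: v for s, v in self.split.items()},
            "features": list(self.features),
            "heads": {},
        }
        if self.de is not None:
            out["de"] = {
                "n_degs": int(len(self.de.degs)),
                "degs": self.de.degs[["gene_id", "log2fc", "p_holm", "status"]]
                .round(12).to_dict("records"),
            }
        if self.selection is not None:
            out["selection"] = self.selection.audit()
        for algo, head in self.heads.items():
            out["heads"][algo] = {
                "params": head["params"],
                "train": head["train"].to_dict(),
                "validation": head["validation"].to_dict(),
            }
        return out

    def summary(self) -> str:
        lines = [f"Pipeline: {len(self.split)} samples "
                 f"({(self.split == 'train').sum()} train / "
                 f"{(self.split == 'validation').sum()} validation)"]
        if self.de is not None:
            lines.append(self.de.summary())
        if self.selection is not None:
            lines.append(self.selection.summary())
        lines.append(f"Model features: {self.features or '(none)'}")
        for algo, head in self.heads.items():
            lines.append(f"  {algo}: train AUC {head['train'].auc:.3f}, "
                         f"validation AUC {head['validation'].auc:.3f}, "
                         f"validation sens {head['validation'].sensitivity:.3f}")
        return "\n".join(lines)


def run_pipeline(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    n_non_validation: int = 6,
    selection_config: SelectionConfig | None = None,
    features: Sequence[str] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
    folds: int = 7,
    seed: int = 0,
    scale_on: str = "train",
    run_de: bool = True,
    run_select: bool = True,
) -> PipelineResult:
    """Run the full analysis on a raw count matrix plus metadata.

    ``features=None`` uses the stability-selection final set; pass an
    explicit list to model predefined markers.  ``scale_on`` is ``train``
    (leakage-safe default) or ``all``.
    """
    split = split_cohort(metadata, n_non_validation)
    meta = metadata.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    labels = meta["group"].to_numpy()
    train_ids = [s for s in matrix.sample_ids if split[s] == "train"]
    valid_ids = [s for s in matrix.sample_ids if split[s] == "validation"]

    logm = log_transform(matrix)
    scaler = fit_scaler(logm, train_ids if scale_on == "train" else None)
    zm = apply_scaler(logm, scaler)
    z_train = zm.subset_samples(train_ids)
    y_train = meta.set_index("sample_id").loc[train_ids, "group"].to_numpy()

    de = DifferentialExpression(logm, meta).fit() if run_de else None

    selection = None
    if run_select and features is None:
        cfg = selection_config or SelectionConfig(base_seed=seed)
        selection = StabilitySelection(z_train, y_train, cfg).fit()
        features = selection.final_features
    features = list(features or [])

    heads: dict = {}
    if features and valid_ids:
        z_valid = zm.subset_samples(valid_ids)
        y_valid = meta.set_index("sample_id").loc[valid_ids, "group"].to_numpy()
        for algo in algorithms:
            res = TranscriptClassifier(z_train, y_train, features, algo,
                                       folds=folds, seed=seed).fit()
            heads[algo] = {
                "params": res.model.params,
                "results": res,
                "train": res.train_report,
                "validation": res.evaluate(z_valid, y_valid),
            }
    return PipelineResult(split, de, selection, features, heads)
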