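"""Expression-matrix container, text IO, and preprocessing.

The pipeline carries transcript abundance through three states: raw
non-negative counts, ``log`` (log2(x+1)) and ``standardized`` (per-gene
z-scores).  Standardization is fit on a sample subset (normally the
training set) so validation samples are scaled with training parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BIOTYPES = ("mRNA", "lncRNA")
VALID_STATES = ("raw", "log", "standardized")


class MatrixFormatError(ValueError):
    """Malformed expression-matrix file or inconsistent matrix contents."""


class TransformStateError(RuntimeError):
    """Operation applied to a matrix in the wrong transform state."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with per-gene biotype labels.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.
    biotypes
        Series mapping gene id -> ``"mRNA"`` or ``"lncRNA"``.
    transform_state
        One of ``"raw"`` (non-negative), ``"log"`` or ``"standardized"``.
    """

    data: pd.DataFrame
    biotypes: pd.Series
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate gene id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample id: {dup!r}")
        if self.transform_state not in VALID_STATES:
            raise MatrixFormatError(
                f"transform_state must be one of {VALID_STATES}, "
                f"got {self.transform_state!r}"
            )
        self.biotypes = self.biotypes.reindex(self.data.index)
        if self.biotypes.isna().any():
            missing = self.biotypes.index[self.biotypes.isna()][0]
            raise MatrixFormatError(f"missing biotype for gene {missing!r}")
        bad = ~self.biotypes.isin(VALID_BIOTYPES)
        if bad.any():
            raise MatrixFormatError(
                f"invalid biotype {self.biotypes[bad].iloc[0]!r}; "
                f"expected one of {VALID_BIOTYPES}"
            )
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise MatrixFormatError("expression values must be finite")
        if self.transform_state == "raw" and (values < 0).any():
            raise MatrixFormatError("raw expression values must be non-negative")

    # -- convenience -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(
            self.data[list(sample_ids)].copy(), self.biotypes.copy(), self.transform_state
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return ExpressionMatrix(
            self.data.loc[list(gene_ids)].copy(),
            self.biotypes.loc[list(gene_ids)].copy(),
            self.transform_state,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.biotypes.copy(), self.transform_state)


# ---------------------------------------------------------------------------
# Text IO
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, transform_state: str = "raw") -> ExpressionMatrix:
    """Read a TSV matrix: columns gene_id, biotype, then one per sample."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise MatrixFormatError(f"{path}: empty file")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "gene_id" or header[1] != "biotype":
            raise MatrixFormatError(
                f"{path}: header must start with 'gene_id\\tbiotype', got {header[:2]}"
            )
        sample_ids = header[2:]
        gene_ids: list[str] = []
        biotypes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            biotypes.append(parts[1])
            try:
                rows.append([float(v) for v in parts[2:]])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: non-numeric value ({exc})")
    data = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    biotype_s = pd.Series(biotypes, index=gene_ids, name="biotype")
    return ExpressionMatrix(data, biotype_s, transform_state)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, digits: int = 10) -> None:
    """Write the TSV layout read back by :func:`read_matrix`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tbiotype\t" + "\t".join(matrix.sample_ids) + "\n")
        fmt = f"%.{digits}g"
        values = matrix.data.to_numpy()
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(fmt % v for v in values[i])
            fh.write(f"{gene}\t{matrix.biotypes.iloc[i]}\t{row}\n")


METADATA_COLUMNS = ["sample_id", "group", "age_days", "weight_kg", "imaging_identifiable"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata CSV and validate the clinical constraints."""
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise MatrixFormatError(f"metadata missing columns: {missing}")
    meta["imaging_identifiable"] = meta["imaging_identifiable"].astype(bool)
    validate_metadata(meta)
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def validate_metadata(metadata: pd.DataFrame) -> None:
    groups = set(metadata["group"].unique())
    bad = groups - {"obstructive", "non_obstructive"}
    if bad:
        raise MatrixFormatError(f"unknown group labels: {sorted(bad)}")
    if metadata["sample_id"].duplicated().any():
        dup = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MatrixFormatError(f"duplicate sample id: {dup!r}")
    if (metadata["age_days"] < 0).any():
        raise MatrixFormatError("age_days must be >= 0")
    # imaging-identifiable obstruction is by definition restricted to cases
    flagged_non = metadata.query("group == 'non_obstructive' and imaging_identifiable")
    if len(flagged_non):
        raise MatrixFormatError(
            "imaging_identifiable may only be set for obstructive samples "
            f"(offending: {flagged_non['sample_id'].iloc[0]!r})"
        )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1), entrywise; requires a raw matrix."""
    if matrix.transform_state != "raw":
        raise TransformStateError(
            f"log_transform requires transform_state 'raw', got {matrix.transform_state!r}"
        )
    return ExpressionMatrix(np.log2(matrix.data + 1.0), matrix.biotypes.copy(), "log")


@dataclass
class Scaler:
    """Per-gene center/scale fitted on a sample subset (n-1 denominator).

    Zero-variance genes are flagged degenerate; applying the scaler maps
    them to all-zeros so gene indices stay aligned downstream.
    """

    center: pd.Series
    scale: pd.Series
    degenerate: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center": self.center, "scale": self.scale, "degenerate": self.degenerate.astype(int)}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "Scaler":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df["center"], df["scale"], df["degenerate"].astype(bool))


def fit_scaler(matrix: ExpressionMatrix, sample_ids: Iterable[str] | None = None) -> Scaler:
    """Fit per-gene mean/sd on ``sample_ids`` (default: all samples)."""
    if matrix.transform_state != "log":
        raise TransformStateError(
            f"fit_scaler requires transform_state 'log', got {matrix.transform_state!r}"
        )
    sub = matrix.data if sample_ids is None else matrix.subset_samples(list(sample_ids)).data
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate a standard deviation")
    center = sub.mean(axis=1)
    scale = sub.std(axis=1, ddof=1)
    degenerate = scale == 0.0
    scale = scale.mask(degenerate, 1.0)  # placeholder; degenerate genes map to 0
    return Scaler(center, scale, degenerate)


def apply_scaler(matrix: ExpressionMatrix, scaler: Scaler) -> ExpressionMatrix:
    if matrix.transform_state != "log":
        raise TransformStateError(
            f"apply_scaler requires transform_state 'log', got {matrix.transform_state!r}"
        )
    if not matrix.data.index.equals(scaler.center.index):
        raise MatrixFormatError("scaler gene ids do not match matrix gene ids")
    z = matrix.data.sub(scaler.center, axis=0).div(scaler.scale, axis=0)
    z.loc[scaler.degenerate] = 0.0
    return ExpressionMatrix(z, matrix.biotypes.copy(), "standardized")


def inverse_scale(matrix: ExpressionMatrix, scaler: Scaler) -> ExpressionMatrix:
    """Undo :func:`apply_scaler` for non-degenerate genes (round-trip check)."""
    if matrix.transform_state != "standardized":
        raise TransformStateError("inverse_scale requires a standardized matrix")
    x = matrix.data.mul(scaler.scale, axis=0).add(scaler.center, axis=0)
    # degenerate genes were zeroed by apply_scaler; restore their constant value
    x.loc[scaler.degenerate] = 0.0
    x.loc[scaler.degenerate] = x.loc[scaler.degenerate].add(
        scaler.center[scaler.degenerate], axis=0
    )
    return ExpressionMatrix(x, matrix.biotypes.copy(), "log")
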