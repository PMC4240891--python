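"""Expression-matrix container and plain-text I/O.

The matrix convention throughout the package is probes (or genes) on the
rows and samples on the columns, holding log2 signal intensities, with an
optional per-sample batch label (the originating dataset in a pooled
cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_matrix_tsv", "write_matrix_tsv"]


class MatrixFormatError(ValueError):
    """Raised when an expression matrix violates its structural contract."""


@dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 intensity matrix with optional batch labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with one column per sample_id.
    batch
        Optional Series mapping sample_id -> batch label. When present it
        must cover exactly the matrix samples.
    """

    values: pd.DataFrame
    batch: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate sample ids: {dups[:5]}")
        self.values = self.values.astype(float)
        if self.batch is not None:
            self.batch = self.batch.reindex(self.values.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise MatrixFormatError(f"samples without batch label: {missing[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        batch = self.batch.loc[sample_ids] if self.batch is not None else None
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], batch)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.batch)

    def is_complete(self) -> bool:
        """True when every entry is finite (no missing intensities)."""
        return bool(np.isfinite(self.values.to_numpy()).all())


def read_matrix_tsv(path: str | Path, metadata: str | Path | None = None) -> ExpressionMatrix:
    """Read a probe-by-sample TSV (first column ``probe_id``).

    ``metadata``, when given, is a CSV with columns sample_id,batch used to
    attach batch labels.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.shape[1] == 0:
        raise MatrixFormatError(f"no sample columns in {path}")
    batch = None
    if metadata is not None:
        meta = pd.read_csv(metadata)
        if not {"sample_id", "batch"} <= set(meta.columns):
            raise MatrixFormatError("sample metadata needs columns sample_id,batch")
        batch = meta.set_index("sample_id")["batch"]
    return ExpressionMatrix(values, batch)


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path,
                     metadata: str | Path | None = None) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
    if metadata is not None and matrix.batch is not None:
        meta = matrix.batch.rename("batch").rename_axis("sample_id").reset_index()
        meta.to_csv(metadata, index=False)
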