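"""Core expression container.

Every pipeline stage consumes and produces an :class:`ExpressionMatrix`:
a genes x samples table of expression values carrying an explicit scale
tag (``"linear"`` intensity/counts or ``"log2"``).  The tag exists so that
transforms which are only meaningful on one scale (log2 transform, fold
normalization, batch scaling) can refuse silently-wrong input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("linear", "log2")


class MatrixError(ValueError):
    """Raised for malformed expression matrices or incompatible operands."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    scale
        ``"linear"`` (non-negative intensities or counts) or ``"log2"``.
    meta
        Free-form metadata propagated by transforms (e.g. the negative
        control background threshold attached by nCounter normalization).
    """

    values: pd.DataFrame
    scale: str = "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise MatrixError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise MatrixError(
                f"missing value at gene {self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        if self.scale == "linear" and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise MatrixError(
                f"negative linear-scale value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise MatrixError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], scale=self.scale, meta=dict(self.meta))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise MatrixError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)], scale=self.scale, meta=dict(self.meta))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), scale=self.scale, meta=dict(self.meta))


def check_same_genes(a: ExpressionMatrix, b: ExpressionMatrix) -> None:
    """Require two matrices to share an identical gene list (same order)."""
    if a.gene_ids != b.gene_ids:
        raise MatrixError("gene lists differ between matrices")


def check_scale(m: ExpressionMatrix, expected: str, what: str) -> None:
    if m.scale != expected:
        raise MatrixError(f"{what} requires a {expected}-scale matrix, got {m.scale!r}")
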