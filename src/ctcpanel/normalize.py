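"""Normalization: quantile, log2, median-to-control folds, batch scaling.

The cross-dataset batch correction mirrors the simplest defensible
protocol for heterogeneous microarray compendia: quantile-normalize
within each study, then rescale each study so that all per-study grand
means coincide.  The correction is a single multiplicative factor per
dataset (target mean / dataset mean), so within-dataset value ratios are
preserved exactly; an additive-offset variant is available via ``mode``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, MatrixError, check_scale


@dataclass
class BatchCorrectionReport:
    dataset_id: str
    pre_mean: float
    scale_factor: float
    post_mean: float


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-mean) value distribution.

    After normalization each sample's sorted value vector equals the
    vector of row means of the column-sorted input, and within-sample rank
    order is preserved.  Ties receive the mean of their tied target
    quantiles (averaged ranks), which makes the transform idempotent.
    """
    arr = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single-sample matrix returned unchanged")
        return matrix.copy()
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_samples):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        scale=matrix.scale,
        meta=dict(matrix.meta),
    )


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """log2(x + pseudocount); flips the scale tag, guarding double transforms.

    Default pseudocount is 0 for strictly positive intensities; use 1 for
    count data so zeros map to 0.
    """
    if matrix.scale == "log2":
        raise MatrixError("matrix is already log2-scaled (double-transform guard)")
    arr = matrix.values.to_numpy(dtype=float) + pseudocount
    if (arr <= 0).any():
        raise MatrixError("log2_transform: non-positive values; increase pseudocount")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr), index=matrix.values.index, columns=matrix.values.columns),
        scale="log2",
        meta=dict(matrix.meta),
    )


def median_normalize_to_controls(
    matrix: ExpressionMatrix,
    controls: ExpressionMatrix,
    pseudocount: float = 0.0,
) -> ExpressionMatrix:
    """Per-gene fold over the median of an independent control set.

    ``fold(g, s) = (x(g,s) + pc) / (median_controls(g) + pc)``.  The output
    is linear-scale, interpreted as fold over control.
    """
    check_scale(matrix, "linear", "median_normalize_to_controls")
    check_scale(controls, "linear", "median_normalize_to_controls (controls)")
    if controls.shape[1] == 0:
        raise MatrixError("empty control set")
    if matrix.gene_ids != controls.gene_ids:
        raise MatrixError("gene lists differ between matrix and controls")
    med = controls.values.median(axis=1).to_numpy() + pseudocount
    if (med <= 0).any():
        raise MatrixError("control median + pseudocount must be positive for fold normalization")
    folds = (matrix.values.to_numpy(dtype=float) + pseudocount) / med[:, None]
    out = ExpressionMatrix(
        pd.DataFrame(folds, index=matrix.values.index, columns=matrix.values.columns),
        scale="linear",
        meta=dict(matrix.meta),
    )
    out.meta["units"] = "fold_over_control_median"
    return out


def batch_scale_correct(
    matrices_by_dataset: dict,
    mode: str = "multiplicative",
) -> tuple[dict, list[BatchCorrectionReport]]:
    """Equalize per-dataset grand means with one scale factor per dataset.

    All matrices must be log2-scale with identical gene lists.  The target
    is the arithmetic mean of the dataset grand means; each dataset is
    multiplied by ``target / grand_mean`` (or shifted by the difference in
    ``mode="additive"``).
    """
    if not matrices_by_dataset:
        raise MatrixError("no datasets to correct")
    if mode not in ("multiplicative", "additive"):
        raise MatrixError(f"unknown batch-correction mode {mode!r}")
    ids = list(matrices_by_dataset)
    genes = matrices_by_dataset[ids[0]].gene_ids
    for did in ids:
        m = matrices_by_dataset[did]
        check_scale(m, "log2", "batch_scale_correct")
        if m.gene_ids != genes:
            raise MatrixError(f"dataset {did}: gene list differs")
    pre_means = {did: float(matrices_by_dataset[did].values.to_numpy().mean()) for did in ids}
    if mode == "multiplicative" and any(v <= 0 for v in pre_means.values()):
        bad = [did for did, v in pre_means.items() if v <= 0]
        raise MatrixError(f"datasets with grand mean <= 0 cannot be scale-corrected: {bad}")
    target = float(np.mean(list(pre_means.values())))
    corrected, reports = {}, []
    for did in ids:
        m = matrices_by_dataset[did]
        if mode == "multiplicative":
            factor = target / pre_means[did]
            values = m.values * factor
        else:
            factor = 1.0
            values = m.values + (target - pre_means[did])
        out = ExpressionMatrix(values, scale="log2", meta=dict(m.meta))
        post = float(out.values.to_numpy().mean())
        corrected[did] = out
        reports.append(BatchCorrectionReport(did, pre_means[did], factor, post))
    return corrected, reports


def batch_reports_frame(reports: list[BatchCorrectionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in reports],
            "pre_mean": [r.pre_mean for r in reports],
            "scale_factor": [r.scale_factor for r in reports],
            "post_mean": [r.post_mean for r in reports],
        }
    )
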