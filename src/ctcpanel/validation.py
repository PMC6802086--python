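"""Panel validation statistics.

Covers the quantities used to validate the panel on independent cohorts:
how many probesets reach a per-sample detection fold anywhere, single
marker dropout fractions (the EpCAM argument against single-marker CTC
capture), per-sample Tukey boxplot summaries of panel-gene log2 values,
and two-group Student t comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, MatrixError, check_scale

P_FLOOR = 2.2e-16  # machine-epsilon reporting convention for tiny p-values


@dataclass
class DetectionReport:
    probesets_total: int
    probesets_detected: int
    fraction_detected: float
    max_fold: pd.Series  # per-probeset max fold over samples


@dataclass
class PanelSummary:
    """Tukey boxplot statistics of panel-gene values for one sample."""

    sample_id: str
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


@dataclass
class GroupComparison:
    t: float
    p: float
    df: float
    p_at_floor: bool  # true when p < 2.2e-16 and is reported at the floor


def count_detected(
    fold_matrix: ExpressionMatrix,
    panel_probesets,
    detection_fold: float = 20.0,
) -> DetectionReport:
    """Count panel probesets reaching ``detection_fold`` in >= 1 sample.

    ``fold_matrix`` holds linear folds over a control median (see
    :func:`ctcpanel.normalize.median_normalize_to_controls`).
    """
    check_scale(fold_matrix, "linear", "count_detected")
    if fold_matrix.shape[1] == 0:
        raise MatrixError("empty sample set")
    panel_probesets = list(panel_probesets)
    missing = [p for p in panel_probesets if p not in fold_matrix.values.index]
    if missing:
        raise MatrixError(f"panel probesets absent from fold matrix: {missing}")
    sub = fold_matrix.values.loc[panel_probesets]
    max_fold = sub.max(axis=1)
    detected = int((max_fold >= detection_fold).sum())
    total = len(panel_probesets)
    return DetectionReport(total, detected, detected / total, max_fold)


def dropout_fraction(
    gene,
    fold_matrix: ExpressionMatrix,
    detection_fold: float = 20.0,
) -> tuple[float, int, int]:
    """Fraction of samples in which ``gene`` stays below the detection fold.

    Returns ``(fraction, n_below, n_samples)``.
    """
    check_scale(fold_matrix, "linear", "dropout_fraction")
    if gene not in fold_matrix.values.index:
        raise MatrixError(f"gene {gene!r} absent from fold matrix")
    row = fold_matrix.values.loc[gene].to_numpy()
    if row.size == 0:
        raise MatrixError("empty sample set")
    below = int((row < detection_fold).sum())
    return below / row.size, below, row.size


def panel_summary(
    log2_matrix: ExpressionMatrix,
    panel_genes,
    whisker: float = 1.5,
) -> list[PanelSummary]:
    """Per-sample Tukey boxplot statistics over the panel genes.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme observed values within ``whisker``*IQR of the quartiles, and
    values beyond are returned as outliers.
    """
    check_scale(log2_matrix, "log2", "panel_summary")
    panel_genes = list(panel_genes)
    missing = [g for g in panel_genes if g not in log2_matrix.values.index]
    if missing:
        raise MatrixError(f"panel genes absent from matrix: {missing}")
    sub = log2_matrix.values.loc[panel_genes]
    summaries = []
    for sample in sub.columns:
        vals = sub[sample].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_limit, hi_limit = q1 - whisker * iqr, q3 + whisker * iqr
        inside = vals[(vals >= lo_limit) & (vals <= hi_limit)]
        wlo, whi = float(inside.min()), float(inside.max())
        outliers = np.sort(vals[(vals < lo_limit) | (vals > hi_limit)])
        summaries.append(PanelSummary(sample, float(med), float(q1), float(q3), wlo, whi, outliers))
    return summaries


def summaries_frame(summaries: list[PanelSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "median": [s.median for s in summaries],
            "q1": [s.q1 for s in summaries],
            "q3": [s.q3 for s in summaries],
            "whisker_low": [s.whisker_low for s in summaries],
            "whisker_high": [s.whisker_high for s in summaries],
            "n_outliers": [len(s.outliers) for s in summaries],
        }
    )


def compare_groups(values_a, values_b, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test (Student pooled-variance by default).

    p-values below 2.2e-16 are reported at that floor with
    ``p_at_floor=True`` (machine-epsilon reporting convention).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise MatrixError("each group needs >= 2 values for a t-test")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    p = float(res.pvalue)
    at_floor = p < P_FLOOR
    return GroupComparison(float(res.statistic), max(p, P_FLOOR) if at_floor else p, df, at_floor)
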