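"""Counting-platform (nCounter-style) lane normalization.

Two sequential per-lane scalings, following the vendor-manual convention:

1. positive-control scaling — each lane is multiplied by
   (mean over lanes of positive-control geometric means) / (lane's
   positive-control geometric mean), removing lane-to-lane technical
   variation (hybridization, binding, imaging);
2. housekeeping scaling — the same construction over the housekeeping
   genes, computed on the already positive-scaled counts, removing
   RNA-input differences.

Scaled counts are then log2(x+1)-transformed.  A background threshold
(mean + 2 SD of the normalized negative-control counts) is attached as
matrix metadata; targets below it in a lane are flagged not-detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CodesetDefinition, CountLane, LoadError
from .matrix import ExpressionMatrix
from .normalize import log2_transform


@dataclass
class LaneFactors:
    lane_id: str
    positive_factor: float
    housekeeping_factor: float
    background_threshold: float


def geometric_mean(counts, zero_policy: str = "replace_with_one") -> float:
    """Geometric mean with a configurable zero policy.

    ``replace_with_one`` (default) substitutes 1 for zeros before the
    product, keeping the mean finite; ``strict`` lets zeros through (the
    mean is then 0).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise LoadError("geometric mean of empty input")
    if (arr < 0).any():
        raise LoadError("geometric mean requires non-negative counts")
    if zero_policy == "replace_with_one":
        arr = np.where(arr == 0, 1.0, arr)
    elif zero_policy != "strict":
        raise LoadError(f"unknown zero policy {zero_policy!r}")
    if (arr == 0).any():
        return 0.0
    return float(np.exp(np.log(arr).mean()))


def _counts_frame(lanes: list[CountLane]) -> pd.DataFrame:
    ids = [lane.lane_id for lane in lanes]
    if len(set(ids)) != len(ids):
        raise LoadError(f"duplicate lane ids: {ids}")
    return pd.DataFrame({lane.lane_id: lane.counts.astype(float) for lane in lanes})


def _control_factors(
    counts: pd.DataFrame,
    control_genes: list,
    reference: str,
) -> pd.Series:
    if not control_genes:
        raise LoadError("codeset defines no control genes for this scaling step")
    geomeans = counts.loc[control_genes].apply(lambda col: geometric_mean(col.to_numpy()))
    if (geomeans <= 0).any():
        bad = geomeans.index[geomeans <= 0].tolist()
        raise LoadError(f"zero control geometric mean in lanes {bad}")
    if reference == "arithmetic":
        ref = float(geomeans.mean())
    elif reference == "geometric":
        ref = geometric_mean(geomeans.to_numpy())
    else:
        raise LoadError(f"unknown reference {reference!r}")
    return ref / geomeans


def positive_control_factors(
    lanes: list[CountLane],
    codeset: CodesetDefinition,
    reference: str = "arithmetic",
) -> pd.Series:
    """Per-lane positive-control scaling factors (reference mean / lane geomean)."""
    counts = _counts_frame(lanes)
    return _control_factors(counts, codeset.genes_with_role("positive_control"), reference)


def housekeeping_factors(
    lanes: list[CountLane],
    codeset: CodesetDefinition,
    positive: pd.Series | None = None,
    reference: str = "arithmetic",
) -> pd.Series:
    """Per-lane housekeeping factors, computed on positive-scaled counts."""
    counts = _counts_frame(lanes)
    if positive is None:
        positive = positive_control_factors(lanes, codeset, reference)
    scaled = counts * positive
    return _control_factors(scaled, codeset.genes_with_role("housekeeping"), reference)


def normalize_lanes(
    lanes: list[CountLane],
    codeset: CodesetDefinition,
    reference: str = "arithmetic",
    n_sd: float = 2.0,
) -> tuple[ExpressionMatrix, list[LaneFactors], float]:
    """Full normalization: positive scaling, housekeeping scaling, log2(x+1).

    Returns the log2 matrix (genes x lanes, all codeset genes), per-lane
    factors, and the negative-control background threshold
    (mean + ``n_sd``*SD of normalized negative-control counts, on the
    linear normalized-count scale, also stored in the matrix ``meta``).
    """
    counts = _counts_frame(lanes)
    pos = positive_control_factors(lanes, codeset, reference)
    hk = housekeeping_factors(lanes, codeset, positive=pos, reference=reference)
    normalized = counts * pos * hk

    neg = normalized.loc[codeset.genes_with_role("negative_control")].to_numpy().ravel()
    threshold = float(neg.mean() + n_sd * neg.std(ddof=0)) if neg.size else 0.0

    linear = ExpressionMatrix(normalized, scale="linear")
    matrix = log2_transform(linear, pseudocount=1.0)
    matrix.meta["background_threshold"] = threshold
    factors = [
        LaneFactors(lane.lane_id, float(pos[lane.lane_id]), float(hk[lane.lane_id]), threshold)
        for lane in lanes
    ]
    return matrix, factors, threshold


def detection_flags(matrix: ExpressionMatrix, threshold: float | None = None) -> pd.DataFrame:
    """Boolean genes x lanes table: normalized counts at/above background.

    ``matrix`` is the log2(x+1) output of :func:`normalize_lanes`; the
    comparison happens on the linear normalized-count scale.
    """
    if threshold is None:
        threshold = matrix.meta.get("background_threshold")
        if threshold is None:
            raise LoadError("no background threshold given or attached to the matrix")
    linear = 2.0 ** matrix.values.to_numpy() - 1.0
    return pd.DataFrame(linear >= threshold, index=matrix.values.index, columns=matrix.values.columns)


def factors_frame(factors: list[LaneFactors]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lane_id": [f.lane_id for f in factors],
            "positive_factor": [f.positive_factor for f in factors],
            "housekeeping_factor": [f.housekeeping_factor for f in factors],
            "background_threshold": [f.background_threshold for f in factors],
        }
    )
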