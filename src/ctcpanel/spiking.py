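"""Spike-in dilution analysis: tumor RNA titrated into a blood RNA pool.

The wet design being modeled: cell-line RNA at masses 10, 1, 0.1, 0.01
and 0.001 ng is mixed into a fixed 100-ng blood RNA pool, in technical
duplicates.  Under the calibration 100 ng == 1e4 cells (10 pg RNA per
cell), the masses correspond to 1e3, 1e2, 10, 1 and 0.1 tumor-cell
equivalents.  Detection at each dilution point is a two-sided pooled
t-test of panel-gene log2 values against unspiked blood replicates; the
limit of detection is the smallest mass starting an unbroken run of
detections up to the largest mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError, check_scale
from .normalize import log2_transform
from .validation import compare_groups

DEFAULT_SPIKE_MASSES_NG = (0.001, 0.01, 0.1, 1.0, 10.0)
DEFAULT_BLOOD_MASS_NG = 100.0
DEFAULT_RNA_PER_CELL_NG = 0.01  # 10 pg/cell: 100 ng == 1e4 cell equivalents


@dataclass
class SpikePoint:
    spike_mass_ng: float
    blood_mass_ng: float
    mass_fraction: float
    ctc_equivalents: float


@dataclass
class SpikeSeries:
    """Dilution ladder metadata for one cell profile."""

    cell_profile: str
    points: list[SpikePoint]
    replicates: int = 2  # technical duplicates
    rna_per_cell_ng: float = DEFAULT_RNA_PER_CELL_NG


def build_series(
    masses_ng=DEFAULT_SPIKE_MASSES_NG,
    blood_mass_ng: float = DEFAULT_BLOOD_MASS_NG,
    rna_per_cell_ng: float = DEFAULT_RNA_PER_CELL_NG,
    cell_profile: str = "cell_line",
    replicates: int = 2,
) -> SpikeSeries:
    points = [
        SpikePoint(
            m,
            blood_mass_ng,
            m / (m + blood_mass_ng),
            ctc_equivalents(m, rna_per_cell_ng),
        )
        for m in sorted(masses_ng)
    ]
    return SpikeSeries(cell_profile, points, replicates, rna_per_cell_ng)


def ctc_equivalents(spike_mass_ng: float, rna_per_cell_ng: float = DEFAULT_RNA_PER_CELL_NG) -> float:
    """Tumor-cell equivalents of an RNA mass (mass / RNA-per-cell)."""
    if spike_mass_ng < 0:
        raise ValueError("spike mass must be non-negative")
    if rna_per_cell_ng <= 0:
        raise ValueError("RNA per cell must be positive")
    return spike_mass_ng / rna_per_cell_ng


def mix_profiles(
    cell_profile: ExpressionMatrix,
    blood_profile: ExpressionMatrix,
    spike_mass_ng: float,
    blood_mass_ng: float,
) -> ExpressionMatrix:
    """Mass-weighted mixture of two linear expression profiles.

    ``mix(g) = (m_spike*cell(g) + m_blood*blood(g)) / (m_spike + m_blood)``
    — per-unit-mass signal of the pooled RNA.
    """
    check_scale(cell_profile, "linear", "mix_profiles")
    check_scale(blood_profile, "linear", "mix_profiles")
    if cell_profile.gene_ids != blood_profile.gene_ids:
        raise MatrixError("gene lists differ between cell and blood profiles")
    total = spike_mass_ng + blood_mass_ng
    if total <= 0:
        raise MatrixError("spike and blood masses are both zero")
    values = (
        spike_mass_ng * cell_profile.values.to_numpy(dtype=float)
        + blood_mass_ng * blood_profile.values.to_numpy(dtype=float)
    ) / total
    return ExpressionMatrix(
        pd.DataFrame(values, index=cell_profile.values.index, columns=cell_profile.values.columns),
        scale="linear",
    )


def _panel_log2_values(matrix: ExpressionMatrix, panel_genes) -> np.ndarray:
    sub = matrix.subset_genes(panel_genes)
    if sub.scale == "linear":
        sub = log2_transform(sub, pseudocount=1.0)
    return sub.values.to_numpy(dtype=float).ravel()


def detect_series(
    series_matrices: dict,
    blood_replicates: ExpressionMatrix,
    panel_genes,
    alpha: float = 0.05,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Per-dilution-point detection table (t, p, detected at ``alpha``).

    ``series_matrices`` maps spike mass (ng) to a replicate matrix of the
    mixed profiles.  By default panel-gene log2 values are pooled within a
    point (duplicates are too few for per-gene testing); ``per_gene=True``
    instead tests each gene and reports the minimum p with its gene.
    """
    blood_vals = _panel_log2_values(blood_replicates, panel_genes)
    rows = []
    for mass in sorted(series_matrices):
        m = series_matrices[mass]
        if m.shape[1] < 2:
            raise MatrixError(f"dilution point {mass} ng needs >= 2 replicates")
        if per_gene:
            blood_sub = blood_replicates.subset_genes(panel_genes)
            if blood_sub.scale == "linear":
                blood_sub = log2_transform(blood_sub, pseudocount=1.0)
            point_sub = m.subset_genes(panel_genes)
            if point_sub.scale == "linear":
                point_sub = log2_transform(point_sub, pseudocount=1.0)
            best = None
            for g in panel_genes:
                cmp = compare_groups(point_sub.values.loc[g], blood_sub.values.loc[g])
                if best is None or cmp.p < best[1].p:
                    best = (g, cmp)
            gene, cmp = best
            rows.append({"spike_mass_ng": mass, "t": cmp.t, "p": cmp.p,
                         "detected": cmp.p < alpha, "gene": gene})
        else:
            cmp = compare_groups(_panel_log2_values(m, panel_genes), blood_vals)
            rows.append({"spike_mass_ng": mass, "t": cmp.t, "p": cmp.p,
                         "detected": cmp.p < alpha})
    return pd.DataFrame(rows)


def limit_of_detection(detection_table: pd.DataFrame) -> float | None:
    """Smallest spike mass starting an unbroken detected run to the top mass.

    Returns ``None`` when no such run exists.
    """
    if len(detection_table) == 0:
        raise MatrixError("empty detection table")
    table = detection_table.sort_values("spike_mass_ng")
    masses = table["spike_mass_ng"].to_numpy()
    detected = table["detected"].to_numpy(dtype=bool)
    lod = None
    for mass, flag in zip(masses[::-1], detected[::-1]):
        if flag:
            lod = float(mass)
        else:
            break
    return lod
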