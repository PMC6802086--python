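"""Marker discovery: blood background estimation, tumor-vs-blood fold
changes, background-gated fold selection, probeset-to-gene collapse.

The selection rule operationalizes "at chip background in blood, high in
tumors": a probeset enters the panel iff its mean blood intensity does
not exceed the estimated chip background AND its linear fold change
(mean tumor / mean blood) reaches ``min_fold``.  Background is a global
quantile of the pooled blood value distribution (a blood-derived ceiling
for "negligible expression"), overridable with a fixed log2 level for
platforms whose noise floor is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError, check_scale


@dataclass
class SelectionConfig:
    """Thresholds of the discovery filter.

    min_fold
        Minimum linear tumor/blood fold for panel entry (default 10; the
        discovered panel spans folds 10-300).
    background_quantile
        Quantile of the pooled blood distribution used as the chip
        background ceiling (default 0.99).
    detection_fold
        Per-sample fold threshold used downstream for detection counts
        (default 20).
    background_level_override
        Optional fixed background on the log2 scale (e.g. 4.0 for count
        data whose blood range sits below 4); overrides the quantile.
    fold_mean
        "arithmetic" (average tumor / average blood, the default) or
        "geometric".
    pseudocount
        Added to means before the fold ratio; default 0 for strictly
        positive intensities.
    """

    min_fold: float = 10.0
    background_quantile: float = 0.99
    detection_fold: float = 20.0
    background_level_override: Optional[float] = None
    fold_mean: str = "arithmetic"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_fold > 1:
            raise ValueError("min_fold must be > 1")
        if not 0 < self.background_quantile <= 1:
            raise ValueError("background_quantile must be in (0, 1]")
        if self.fold_mean not in ("arithmetic", "geometric"):
            raise ValueError("fold_mean must be 'arithmetic' or 'geometric'")


@dataclass
class MarkerPanel:
    """Selected probesets with their evidence and selection provenance."""

    entries: pd.DataFrame  # probeset_id, gene_symbol, blood_mean, tumor_mean, fold_change, at_background_in_blood
    provenance: dict = field(default_factory=dict)

    @property
    def probeset_ids(self) -> list:
        return self.entries["probeset_id"].tolist()

    @property
    def gene_symbols(self) -> list:
        return [g for g in self.entries["gene_symbol"].unique() if g is not None]

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        cols = ["probeset_id", "gene_symbol", "blood_mean", "tumor_mean", "fold_change"]
        self.entries[cols].to_csv(path, index=False)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
            fh.write("\n")


def estimate_background(blood: ExpressionMatrix, config: SelectionConfig) -> float:
    """Chip background level (linear intensity) from pooled blood values."""
    check_scale(blood, "linear", "estimate_background")
    if blood.shape[0] == 0 or blood.shape[1] == 0:
        raise MatrixError("empty blood matrix")
    if config.background_level_override is not None:
        return float(2.0 ** config.background_level_override)
    return float(np.quantile(blood.values.to_numpy().ravel(), config.background_quantile))


def compute_fold_changes(
    tumor: ExpressionMatrix,
    blood: ExpressionMatrix,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Per-probeset blood mean, tumor mean and linear fold (tumor/blood)."""
    config = config or SelectionConfig()
    check_scale(tumor, "linear", "compute_fold_changes")
    check_scale(blood, "linear", "compute_fold_changes")
    if tumor.gene_ids != blood.gene_ids:
        raise MatrixError("gene lists differ between tumor and blood matrices")
    if config.fold_mean == "arithmetic":
        t_mean = tumor.values.mean(axis=1).to_numpy()
        b_mean = blood.values.mean(axis=1).to_numpy()
    else:
        t_mean = np.exp(np.log(tumor.values.to_numpy() + config.pseudocount).mean(axis=1))
        b_mean = np.exp(np.log(blood.values.to_numpy() + config.pseudocount).mean(axis=1))
    fold = (t_mean + config.pseudocount) / (b_mean + config.pseudocount)
    return pd.DataFrame(
        {
            "probeset_id": tumor.gene_ids,
            "blood_mean": b_mean,
            "tumor_mean": t_mean,
            "fold_change": fold,
        }
    )


def select_markers(
    fold_table: pd.DataFrame,
    background: float,
    config: SelectionConfig | None = None,
) -> MarkerPanel:
    """Background-gated fold filter; an empty panel is a valid result.

    Entries are ordered by descending fold, ties broken by probeset id.
    """
    config = config or SelectionConfig()
    at_bg = fold_table["blood_mean"].to_numpy() <= background
    keep = at_bg & (fold_table["fold_change"].to_numpy() >= config.min_fold)
    entries = fold_table.loc[keep].copy()
    entries["at_background_in_blood"] = True
    entries["gene_symbol"] = None
    entries = entries.sort_values(
        ["fold_change", "probeset_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    provenance = {
        "background": background,
        "config": vars(config).copy(),
        "n_candidates": int(len(fold_table)),
        "n_selected": int(len(entries)),
    }
    cols = ["probeset_id", "gene_symbol", "blood_mean", "tumor_mean",
            "fold_change", "at_background_in_blood"]
    return MarkerPanel(entries[cols], provenance)


def collapse_probesets(panel: MarkerPanel, annotation: pd.DataFrame) -> MarkerPanel:
    """Collapse probeset-level entries to one entry per gene symbol.

    Keeps the max-fold probeset per gene (ties: lexicographically smallest
    probeset id).  Every panel probeset must be annotated.
    """
    mapping = dict(zip(annotation["probeset_id"], annotation["gene_symbol"]))
    missing = [p for p in panel.entries["probeset_id"] if p not in mapping]
    if missing:
        raise MatrixError(f"unannotated probesets: {missing}")
    entries = panel.entries.copy()
    entries["gene_symbol"] = entries["probeset_id"].map(mapping)
    entries = entries.sort_values(
        ["fold_change", "probeset_id"], ascending=[False, True], kind="mergesort"
    )
    collapsed = entries.drop_duplicates("gene_symbol", keep="first").reset_index(drop=True)
    provenance = dict(panel.provenance)
    provenance["collapsed"] = {"n_probesets": int(len(panel)), "n_genes": int(len(collapsed))}
    return MarkerPanel(collapsed, provenance)
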