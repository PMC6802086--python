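"""On-disk formats and cohort-manifest validation.

Formats (all plain text):

* expression matrices — TSV, first header token ``gene_id``, one column per
  sample; ``#``-prefixed comment lines ignored;
* sample manifests — CSV with columns
  ``sample_id,dataset_id,tissue_class,cancer_type``;
* probeset annotation — CSV ``probeset_id,gene_symbol``;
* codeset definition — CSV ``gene_id,role``;
* count lanes — simplified two-section CSV: a header attribute block
  (``key,value`` lines) followed by a ``gene_id,role,count`` section.  A
  reader hook point is left for vendor lane files (pass a custom parser to
  :func:`read_count_lanes`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError

TISSUE_CLASSES = (
    "blood",
    "pbmc",
    "tumor_biopsy",
    "cell_line",
    "ctc",
    "adjacent_tissue",
    "benign_lesion",
)

CODESET_ROLES = (
    "target",
    "housekeeping",
    "positive_control",
    "negative_control",
    "clinical_biomarker",
)


class LoadError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, scale: str = "linear", drop_missing: bool = False) -> ExpressionMatrix:
    """Load a TSV expression matrix and tag it with the declared scale.

    Missing values are rejected by default; with ``drop_missing=True`` genes
    containing any missing value are dropped instead.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.name != "gene_id":
        raise LoadError(f"{path}: first header token must be 'gene_id', got {df.index.name!r}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicate gene ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise LoadError(f"{path}: duplicate sample ids {dups}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError):
        for g in df.index:
            for s in df.columns:
                try:
                    float(df.at[g, s])
                except (TypeError, ValueError):
                    raise LoadError(f"{path}: non-numeric cell at gene {g!r}, sample {s!r}") from None
        raise
    if values.isna().to_numpy().any():
        if drop_missing:
            values = values.dropna(axis=0)
        else:
            g = values.index[values.isna().any(axis=1)][0]
            raise LoadError(f"{path}: missing value in gene {g!r} (pass drop_missing=True to drop)")
    try:
        return ExpressionMatrix(values, scale=scale)
    except MatrixError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    # repr-roundtrip precision so write->read is identity
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path) -> pd.DataFrame:
    """Load a sample manifest CSV and validate the tissue-class vocabulary."""
    df = pd.read_csv(path, dtype=str)
    required = ["sample_id", "dataset_id", "tissue_class", "cancer_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise LoadError(f"{path}: duplicate sample ids {dups}")
    bad = sorted(set(df["tissue_class"]) - set(TISSUE_CLASSES))
    if bad:
        raise LoadError(f"{path}: unknown tissue classes {bad}; expected {TISSUE_CLASSES}")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def check_manifest_matches_matrix(manifest: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    """Every sample of a paired matrix must appear exactly once in the manifest."""
    in_manifest = set(manifest["sample_id"])
    missing = [s for s in matrix.sample_ids if s not in in_manifest]
    if missing:
        raise LoadError(f"matrix samples absent from manifest: {missing}")


def validate_manifest(manifest: pd.DataFrame, expected_totals: dict | None = None) -> dict:
    """Tabulate a manifest and compare against declared totals.

    ``expected_totals`` keys may be dataset ids, tissue classes, or the
    special key ``"total"``.  Mismatches are reported, not fatal.

    Returns a JSON-serializable report with per-dataset counts, per
    tissue-class counts, the grand total, and a mismatch list.
    """
    if len(manifest) == 0:
        raise LoadError("empty manifest")
    per_dataset = manifest.groupby("dataset_id").size().to_dict()
    per_tissue = manifest.groupby("tissue_class").size().to_dict()
    report = {
        "per_dataset": {k: int(v) for k, v in sorted(per_dataset.items())},
        "per_tissue_class": {k: int(v) for k, v in sorted(per_tissue.items())},
        "total": int(len(manifest)),
        "mismatches": [],
    }
    for key, expected in (expected_totals or {}).items():
        if key == "total":
            actual = report["total"]
        elif key in report["per_dataset"]:
            actual = report["per_dataset"][key]
        elif key in report["per_tissue_class"]:
            actual = report["per_tissue_class"][key]
        else:
            actual = 0
        if actual != expected:
            report["mismatches"].append({"key": key, "expected": int(expected), "actual": int(actual)})
    return report


def write_manifest_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


# ---------------------------------------------------------------------------
# probeset annotation


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["probeset_id", "gene_symbol"]:
        raise LoadError(f"{path}: expected columns probeset_id,gene_symbol")
    if df["probeset_id"].duplicated().any():
        dups = df.loc[df["probeset_id"].duplicated(), "probeset_id"].tolist()
        raise LoadError(f"{path}: duplicate probeset ids {dups}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# codeset


@dataclass
class CodesetDefinition:
    """Gene roles for the counting platform.

    ``roles`` maps gene id -> role; roles partition the gene list.  The
    production panel has 80 targets, 7 housekeeping, 5 positive controls,
    8 negative controls and 4 clinical biomarkers (104 genes).
    """

    roles: dict

    def __post_init__(self) -> None:
        bad = sorted({r for r in self.roles.values()} - set(CODESET_ROLES))
        if bad:
            raise LoadError(f"unknown codeset roles {bad}; expected {CODESET_ROLES}")

    @property
    def gene_ids(self) -> list:
        return list(self.roles)

    def genes_with_role(self, role: str) -> list:
        if role not in CODESET_ROLES:
            raise LoadError(f"unknown role {role!r}")
        return [g for g, r in self.roles.items() if r == role]

    @property
    def size(self) -> int:
        return len(self.roles)

    def role_counts(self) -> dict:
        counts = {r: 0 for r in CODESET_ROLES}
        for r in self.roles.values():
            counts[r] += 1
        return counts


def read_codeset(path) -> CodesetDefinition:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["gene_id", "role"]:
        raise LoadError(f"{path}: expected columns gene_id,role")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise LoadError(f"{path}: duplicate codeset genes {dups}")
    return CodesetDefinition(dict(zip(df["gene_id"], df["role"])))


def write_codeset(codeset: CodesetDefinition, path) -> None:
    pd.DataFrame(
        {"gene_id": list(codeset.roles), "role": list(codeset.roles.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count lanes


@dataclass
class CountLane:
    """One counting-platform lane: integer counts over the codeset genes."""

    lane_id: str
    counts: pd.Series  # indexed by gene id, aligned to the codeset order
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            g = self.counts.index[np.argwhere(arr < 0)[0][0]]
            raise LoadError(f"lane {self.lane_id}: negative count for gene {g!r}")


def _parse_lane_csv(path) -> tuple[dict, pd.Series]:
    attributes: dict = {}
    genes: list = []
    counts: list = []
    section = "attributes"
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts[0] == "gene_id":  # section header row
            section = "counts"
            continue
        if section == "attributes":
            if len(parts) < 2:
                raise LoadError(f"{path}: malformed attribute line {line!r}")
            attributes[parts[0]] = ",".join(parts[1:])
        else:
            if len(parts) != 3:
                raise LoadError(f"{path}: malformed count line {line!r}")
            gene, _role, count = parts
            try:
                value = float(count)
            except ValueError:
                raise LoadError(f"{path}: non-numeric count for gene {gene!r}") from None
            if value != int(value):
                raise LoadError(f"{path}: fractional count {value} for gene {gene!r}")
            genes.append(gene)
            counts.append(int(value))
    return attributes, pd.Series(counts, index=genes, dtype=int)


def read_count_lanes(
    paths: Sequence,
    codeset: CodesetDefinition,
    parser: Callable | None = None,
) -> list[CountLane]:
    """Read per-lane count CSVs, aligning every lane to the codeset order.

    ``parser`` may replace the built-in two-section CSV parser (hook point
    for vendor lane files); it must return ``(attributes, counts_series)``.
    """
    parse = parser or _parse_lane_csv
    lanes = []
    for path in paths:
        attributes, counts = parse(path)
        missing = [g for g in codeset.gene_ids if g not in counts.index]
        if missing:
            raise LoadError(f"{path}: lane missing codeset genes {missing}")
        extra = [g for g in counts.index if g not in codeset.roles]
        if extra:
            raise LoadError(f"{path}: lane has genes outside the codeset {extra}")
        lane_id = attributes.get("lane_id", Path(path).stem)
        lanes.append(CountLane(lane_id, counts.loc[codeset.gene_ids], attributes))
    return lanes


def write_count_lane(lane: CountLane, codeset: CodesetDefinition, path) -> None:
    with open(path, "w") as fh:
        attrs = dict(lane.attributes)
        attrs.setdefault("lane_id", lane.lane_id)
        for key, value in attrs.items():
            fh.write(f"{key},{value}\n")
        fh.write("gene_id,role,count\n")
        for gene in codeset.gene_ids:
            fh.write(f"{gene},{codeset.roles[gene]},{int(lane.counts[gene])}\n")
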