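"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the structure the pipeline was built for:

* discovery matrices — blood/PBMC samples log-normal around a chip
  background (log2 mean 3, sd 0.5, keeping blood below 4); a planted set
  of 85 marker probesets (mapping to 80 genes; five genes carry two
  probesets) whose tumor linear fold over blood is drawn uniformly from
  10-300, all other genes at background everywhere;
* batched datasets — 17 studies with planted multiplicative offsets on
  the log2 values, for exercising scale-factor batch correction;
* counting-platform runs — Poisson counts over a 104-gene codeset
  (80 targets, 7 housekeeping, 5 positive controls, 8 negative controls,
  4 clinical biomarkers) with planted per-lane technical factors;
  group-level target log2 levels: tumors 8-10, cell lines 6-9, benign
  lesions 6.5-9, blood around 3;
* spike-in series — mass-weighted mixtures of a cell-line profile into a
  flat 100-ng blood pool at masses 0.001-10 ng, technical duplicates.

Planted folds are exact empirical folds: marker rows are rescaled so the
realized linear-mean ratio equals the drawn fold, so recovery tests are
properties of the selector rather than of Monte Carlo luck.  Every
generator is a pure function of its config (seeded); re-runs are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CodesetDefinition,
    CountLane,
    write_annotation,
    write_codeset,
    write_count_lane,
    write_expression_matrix,
    write_manifest,
)
from .matrix import ExpressionMatrix
from .spiking import (
    DEFAULT_BLOOD_MASS_NG,
    DEFAULT_SPIKE_MASSES_NG,
    mix_profiles,
)

CLINICAL_BIOMARKERS = ("ESR1", "PGR", "ERBB2", "PRLR")
POSITIVE_CONTROL_LADDER = (8192.0, 2048.0, 512.0, 128.0, 32.0)
NEGATIVE_CONTROL_LEVEL = 1.5
HOUSEKEEPING_LEVEL = 512.0

GROUP_LOG2_RANGES = {
    "tumor": (8.0, 10.0),
    "benign": (6.5, 9.0),
    "cell_line": (6.0, 9.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Cohort sizes default to the discovery-stage composition (417 tumors,
    41 cell lines, 401 blood); expression levels and fold ranges default
    to the reported ones (marker folds 10-300, blood log2 background
    3.0 +/- 0.5, tumor panel log2 8-10, cell lines 6-9).  The spike-in
    cell profile defaults to log2 9-10.5, the pure-cell panel level
    implied by the observed mixture interquartile levels (about 4 at 1 ng
    and 6 at 10 ng over a 100-ng blood pool).
    """

    n_genes: int = 2000
    n_marker_probesets: int = 85
    n_marker_genes: int = 80
    fold_range: tuple = (10.0, 300.0)
    blood_log2_mean: float = 3.0
    blood_log2_sd: float = 0.5
    tumor_log2_range: tuple = GROUP_LOG2_RANGES["tumor"]
    cell_line_log2_range: tuple = GROUP_LOG2_RANGES["cell_line"]
    spike_cell_log2_range: tuple = (9.0, 10.5)
    n_tumor: int = 417
    n_cell_line: int = 41
    n_blood: int = 401
    n_pbmc: int = 26
    n_datasets: int = 17
    samples_per_dataset: int = 20
    batch_factor_range: tuple = (0.8, 1.25)
    lane_factor_range: tuple = (0.7, 1.3)
    noise_log2_sd: float = 0.5
    technical_log2_sd: float = 0.15
    spike_masses_ng: tuple = DEFAULT_SPIKE_MASSES_NG
    spike_blood_mass_ng: float = DEFAULT_BLOOD_MASS_NG
    spike_replicates: int = 2
    spike_blood_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_marker_genes <= self.n_marker_probesets <= self.n_genes:
            raise ValueError("need n_marker_genes <= n_marker_probesets <= n_genes")
        if self.fold_range[0] < 1:
            raise ValueError("fold_range minimum must be >= 1")
        if self.n_marker_probesets - self.n_marker_genes > self.n_marker_genes:
            raise ValueError("more duplicate probesets than marker genes")


@dataclass
class PlantedTruth:
    """Ground truth serialized beside generated artifacts."""

    marker_probesets: list = field(default_factory=list)
    probeset_to_gene: dict = field(default_factory=dict)
    marker_folds: dict = field(default_factory=dict)
    batch_factors: dict = field(default_factory=dict)
    lane_factors: dict = field(default_factory=dict)
    spike_masses_ng: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# discovery


@dataclass
class DiscoveryData:
    tumor: ExpressionMatrix
    cell_line: ExpressionMatrix
    blood: ExpressionMatrix
    pbmc: ExpressionMatrix
    manifest: pd.DataFrame
    annotation: pd.DataFrame
    truth: PlantedTruth


def _background_matrix(rng, config: GeneratorConfig, n_samples: int, prefix: str) -> pd.DataFrame:
    values = 2.0 ** rng.normal(
        config.blood_log2_mean, config.blood_log2_sd, size=(config.n_genes, n_samples)
    )
    cols = [f"{prefix}{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(values, columns=cols)


def generate_discovery_dataset(config: GeneratorConfig | None = None) -> DiscoveryData:
    """Tumor/cell-line/blood/PBMC matrices with planted markers.

    Marker probesets get tumor levels whose empirical linear fold over the
    blood mean equals a fold drawn uniformly from ``fold_range``; in cell
    lines they sit in the cell-line log2 range.  Non-markers are at blood
    background in every tissue.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    probesets = [f"PS{i:05d}" for i in range(config.n_genes)]
    marker_idx = np.sort(rng.choice(config.n_genes, config.n_marker_probesets, replace=False))
    marker_probesets = [probesets[i] for i in marker_idx]

    # 85 -> 80 mapping: the surplus probesets double up on the first genes
    n_dup = config.n_marker_probesets - config.n_marker_genes
    marker_genes = [f"MG{i:04d}" for i in range(config.n_marker_genes)]
    probeset_to_gene = {}
    for k, ps in enumerate(marker_probesets):
        gene = marker_genes[k] if k < config.n_marker_genes else marker_genes[k - config.n_marker_genes]
        probeset_to_gene[ps] = gene
    other = 0
    for ps in probesets:
        if ps not in probeset_to_gene:
            probeset_to_gene[ps] = f"NG{other:05d}"
            other += 1
    annotation = pd.DataFrame(
        {"probeset_id": probesets, "gene_symbol": [probeset_to_gene[p] for p in probesets]}
    )

    blood = _background_matrix(rng, config, config.n_blood, "BLOOD-")
    pbmc = _background_matrix(rng, config, config.n_pbmc, "PBMC-")
    tumor = _background_matrix(rng, config, config.n_tumor, "TUMOR-")
    cell = _background_matrix(rng, config, config.n_cell_line, "LINE-")
    for df, prefix in ((blood, None), (pbmc, None), (tumor, None), (cell, None)):
        df.index = probesets

    folds = rng.uniform(config.fold_range[0], config.fold_range[1], size=config.n_marker_probesets)
    blood_means = blood.mean(axis=1)
    for i, ps in zip(marker_idx, range(config.n_marker_probesets)):
        f = folds[ps]
        gene_id = probesets[i]
        level = config.blood_log2_mean + np.log2(f)
        draw = 2.0 ** rng.normal(level, config.noise_log2_sd, size=config.n_tumor)
        # exact empirical fold: rescale so mean(tumor row)/mean(blood row) == f
        draw *= (f * blood_means[gene_id]) / draw.mean()
        tumor.loc[gene_id] = draw
        cell_level = rng.uniform(*config.cell_line_log2_range)
        cell.loc[gene_id] = 2.0 ** rng.normal(cell_level, config.noise_log2_sd, size=config.n_cell_line)

    matrices = {
        "tumor": (tumor, "SYN-TUMOR", "tumor_biopsy", "breast"),
        "cell_line": (cell, "SYN-LINES", "cell_line", "breast"),
        "blood": (blood, "SYN-BLOOD", "blood", "none"),
        "pbmc": (pbmc, "SYN-PBMC", "pbmc", "none"),
    }
    rows = []
    for _, (df, dataset, tissue, cancer) in matrices.items():
        for s in df.columns:
            rows.append({"sample_id": s, "dataset_id": dataset, "tissue_class": tissue, "cancer_type": cancer})
    manifest = pd.DataFrame(rows)

    truth = PlantedTruth(
        marker_probesets=marker_probesets,
        probeset_to_gene={p: probeset_to_gene[p] for p in marker_probesets},
        marker_folds={ps: float(folds[k]) for k, ps in enumerate(marker_probesets)},
    )
    return DiscoveryData(
        tumor=ExpressionMatrix(tumor, scale="linear"),
        cell_line=ExpressionMatrix(cell, scale="linear"),
        blood=ExpressionMatrix(blood, scale="linear"),
        pbmc=ExpressionMatrix(pbmc, scale="linear"),
        manifest=manifest,
        annotation=annotation,
        truth=truth,
    )


def write_discovery_dataset(data: DiscoveryData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("tumor", "cell_line", "blood", "pbmc"):
        write_expression_matrix(getattr(data, name), outdir / f"{name}.tsv")
    write_manifest(data.manifest, outdir / "manifest.csv")
    write_annotation(data.annotation, outdir / "annotation.csv")
    data.truth.write(outdir / "truth.json")


# ---------------------------------------------------------------------------
# batched datasets


def generate_batched_datasets(
    config: GeneratorConfig | None = None,
    base_log2_mean: float = 6.0,
) -> tuple[dict, PlantedTruth]:
    """Log2 matrices for ``n_datasets`` studies with planted scale offsets.

    Each study's base grand mean is pinned exactly to ``base_log2_mean``
    before its planted factor is applied, so recovered correction factors
    are exactly proportional to the inverse planted factors.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    genes = [f"PS{i:05d}" for i in range(config.n_genes)]
    factors = rng.uniform(*config.batch_factor_range, size=config.n_datasets)
    matrices, truth_factors = {}, {}
    for d in range(config.n_datasets):
        did = f"DS{d:02d}"
        base = rng.normal(base_log2_mean, 1.0, size=(config.n_genes, config.samples_per_dataset))
        base *= base_log2_mean / base.mean()
        values = base * factors[d]
        cols = [f"{did}-s{i:03d}" for i in range(config.samples_per_dataset)]
        matrices[did] = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), scale="log2")
        truth_factors[did] = float(factors[d])
    return matrices, PlantedTruth(batch_factors=truth_factors)


# ---------------------------------------------------------------------------
# counting-platform runs


def default_codeset(n_targets: int = 80) -> CodesetDefinition:
    """The 104-gene codeset layout: targets + 7 HK + 5 pos + 8 neg + 4 clinical."""
    roles = {}
    for i in range(n_targets):
        roles[f"MG{i:04d}"] = "target"
    for i in range(7):
        roles[f"HK{i + 1}"] = "housekeeping"
    for i in range(5):
        roles[f"POS_{chr(65 + i)}"] = "positive_control"
    for i in range(8):
        roles[f"NEG_{chr(65 + i)}"] = "negative_control"
    for name in CLINICAL_BIOMARKERS:
        roles[name] = "clinical_biomarker"
    return CodesetDefinition(roles)


DEFAULT_NCOUNTER_GROUPS = {"tumor": 36, "benign": 8, "cell_line": 8, "blood": 32}


@dataclass
class NCounterRun:
    lanes: list
    codeset: CodesetDefinition
    groups: dict  # lane_id -> group name
    truth: PlantedTruth


def generate_ncounter_run(
    config: GeneratorConfig | None = None,
    codeset: CodesetDefinition | None = None,
    groups: dict | None = None,
) -> NCounterRun:
    """Poisson count lanes with planted per-lane technical factors.

    ``groups`` maps a group name (``tumor``, ``benign``, ``cell_line``,
    ``blood``) to its number of lanes.  Target and clinical-biomarker
    levels are drawn per gene from the group's log2 range (blood: normal
    around the background); housekeeping genes are constant across
    biology; positive controls follow a fixed ladder; negative controls
    sit near zero.
    """
    config = config or GeneratorConfig()
    codeset = codeset or default_codeset()
    groups = dict(groups or DEFAULT_NCOUNTER_GROUPS)
    for role in ("target", "housekeeping", "positive_control", "negative_control"):
        if not codeset.genes_with_role(role):
            raise ValueError(f"codeset missing role {role!r}")
    rng = np.random.default_rng(config.seed)

    targets = codeset.genes_with_role("target") + codeset.genes_with_role("clinical_biomarker")
    hk = codeset.genes_with_role("housekeeping")
    pos = codeset.genes_with_role("positive_control")
    neg = codeset.genes_with_role("negative_control")

    # per-group, per-gene expected log2 levels (fixed across lanes)
    group_levels = {}
    for group in groups:
        if group == "blood":
            levels = rng.normal(config.blood_log2_mean, config.blood_log2_sd, size=len(targets))
        else:
            lo, hi = GROUP_LOG2_RANGES[group]
            levels = rng.uniform(lo, hi, size=len(targets))
        group_levels[group] = pd.Series(levels, index=targets)

    lanes, lane_groups, lane_factors = [], {}, {}
    for group, n_lanes in groups.items():
        for i in range(n_lanes):
            lane_id = f"{group}-{i:02d}"
            factor = rng.uniform(*config.lane_factor_range)
            expected = pd.Series(0.0, index=codeset.gene_ids)
            noise = 2.0 ** rng.normal(0.0, config.technical_log2_sd, size=len(targets))
            expected[targets] = 2.0 ** group_levels[group][targets].to_numpy() * noise
            expected[hk] = HOUSEKEEPING_LEVEL
            expected[pos] = POSITIVE_CONTROL_LADDER[: len(pos)]
            expected[neg] = NEGATIVE_CONTROL_LEVEL
            counts = pd.Series(
                rng.poisson(factor * expected.to_numpy()), index=codeset.gene_ids, dtype=int
            )
            lanes.append(CountLane(lane_id, counts, {"lane_id": lane_id, "group": group}))
            lane_groups[lane_id] = group
            lane_factors[lane_id] = float(factor)

    truth = PlantedTruth(lane_factors=lane_factors)
    return NCounterRun(lanes, codeset, lane_groups, truth)


def write_ncounter_run(run: NCounterRun, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_codeset(run.codeset, outdir / "codeset.csv")
    paths = []
    for lane in run.lanes:
        path = outdir / f"{lane.lane_id}.csv"
        write_count_lane(lane, run.codeset, path)
        paths.append(path)
    run.truth.write(outdir / "truth.json")
    return paths


# ---------------------------------------------------------------------------
# spike-in series


@dataclass
class SpikeData:
    series: dict  # spike mass (ng) -> replicate ExpressionMatrix (linear)
    blood: ExpressionMatrix  # unspiked blood-pool replicates
    cell_profile: ExpressionMatrix
    blood_profile: ExpressionMatrix
    panel_genes: list
    truth: PlantedTruth


def generate_spike_series(config: GeneratorConfig | None = None) -> SpikeData:
    """Dilution-series replicate matrices over the panel genes.

    The blood pool is a single physical sample with every panel gene at
    the background level (2^blood_log2_mean); the cell profile draws each
    panel gene from ``spike_cell_log2_range``.  Replicates add log-normal
    technical noise (sd ``technical_log2_sd``) to the mass-weighted
    mixture.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    genes = [f"MG{i:04d}" for i in range(config.n_marker_genes)]

    blood_profile = ExpressionMatrix(
        pd.DataFrame({"blood_pool": np.full(len(genes), 2.0 ** config.blood_log2_mean)}, index=genes),
        scale="linear",
    )
    cell_levels = rng.uniform(*config.spike_cell_log2_range, size=len(genes))
    cell_profile = ExpressionMatrix(
        pd.DataFrame({"cell_pool": 2.0 ** cell_levels}, index=genes), scale="linear"
    )

    def replicate(profile_values: np.ndarray, label: str, n: int) -> ExpressionMatrix:
        noise = 2.0 ** rng.normal(0.0, config.technical_log2_sd, size=(len(genes), n))
        values = profile_values[:, None] * noise
        cols = [f"{label}-r{i}" for i in range(n)]
        return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), scale="linear")

    series = {}
    for mass in sorted(config.spike_masses_ng):
        mix = mix_profiles(cell_profile, blood_profile, mass, config.spike_blood_mass_ng)
        series[float(mass)] = replicate(
            mix.values.to_numpy().ravel(), f"spike{mass:g}ng", config.spike_replicates
        )
    blood = replicate(
        blood_profile.values.to_numpy().ravel(), "blood", config.spike_blood_replicates
    )
    truth = PlantedTruth(spike_masses_ng=[float(m) for m in sorted(config.spike_masses_ng)])
    return SpikeData(series, blood, cell_profile, blood_profile, genes, truth)


def write_spike_series(data: SpikeData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mass, matrix in data.series.items():
        write_expression_matrix(matrix, outdir / f"spike_{mass:g}ng.tsv")
    write_expression_matrix(data.blood, outdir / "blood_replicates.tsv")
    write_expression_matrix(data.cell_profile, outdir / "cell_profile.tsv")
    write_expression_matrix(data.blood_profile, outdir / "blood_profile.tsv")
    pd.DataFrame(
        {"mass_ng": list(data.series), "replicate": [m.shape[1] for m in data.series.values()]}
    ).to_csv(outdir / "series.csv", index=False)
    data.truth.write(outdir / "truth.json")
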