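"""Published cohort composition of the 80-gene panel study.

The panel was discovered by comparing breast tumor biopsies and breast
cell lines against blood from donors with conditions other than cancer,
then validated externally (breast tumors, cell lines, eight cancer types,
a pancreatic CTC set) and experimentally on a counting platform.  This
module encodes the cohort table — dataset accessions, tissue classes and
sample counts — so that manifest arithmetic (group totals, the grand
total) can be recomputed from an explicit per-sample manifest rather than
asserted.

Accessions are treated as opaque dataset identifiers.  Where the source
table gives only a group total across several accessions (the 3601-sample
eight-cancer-type group spans 17 accessions), samples are distributed
round-robin; only group totals are ever checked.
"""

from __future__ import annotations

import pandas as pd

# (group, [dataset ids], tissue_class, cancer_type, n_samples)
COHORTS = [
    ("discovery_blood", ["GSE5418", "GSE12288", "GSE1343", "GSE3846", "GSE6269"],
     "blood", "none", 401),
    ("discovery_breast_biopsies", ["GSE2034", "HESS2006"], "tumor_biopsy", "breast", 417),
    ("discovery_breast_cell_lines", ["GSE16795", "GSE8096"], "cell_line", "breast", 41),
    ("validation_whole_blood", ["GSE19314"], "blood", "none", 66),
    ("validation_pbmc", ["GSE11281", "GSE11881"], "pbmc", "none", 26),
    ("validation_microdissected_biopsies", ["GSE18864"], "tumor_biopsy", "breast", 70),
    ("validation_fine_needle_aspirates", ["GSE20194"], "tumor_biopsy", "breast", 278),
    ("validation_eight_cancer_types",
     ["GSE25055", "GSE39582", "GSE68468", "GSE13911", "GSE54129", "GSE13159",
      "GSE14471", "GSE19188", "GSE30219", "GSE26712", "GSE9891", "GSE15471",
      "GSE16515", "GSE17951", "GSE8218", "E-TABM-157", "GSE27562"],
     "tumor_biopsy", "mixed", 3601),
    ("validation_pancreatic_ctc", ["GSE18670"], "ctc", "pancreatic", 24),
    # counting-platform experimental validation: 44 breast lesions, 32 buffy
    # coats, 8 cell lines, 10 spiking samples, 10 matched tumor/blood pairs
    ("experimental_breast_lesions", ["NCOUNTER-LESIONS"], "tumor_biopsy", "breast", 44),
    ("experimental_buffy_coats", ["NCOUNTER-BLOOD"], "blood", "none", 32),
    ("experimental_cell_lines", ["NCOUNTER-LINES"], "cell_line", "breast", 8),
    ("experimental_spiking", ["NCOUNTER-SPIKE"], "blood", "none", 10),
    ("experimental_matched_pairs", ["NCOUNTER-MATCHED"], "tumor_biopsy", "mixed", 10),
]

DISCOVERY_GROUPS = ("discovery_blood", "discovery_breast_biopsies", "discovery_breast_cell_lines")
BREAST_VALIDATION_GROUPS = ("validation_microdissected_biopsies", "validation_fine_needle_aspirates")
# 15 cancer accessions + the 51-cell-line set + the blood/PBMC set
N_BATCH_DATASETS = 17


def study_manifest() -> pd.DataFrame:
    """Per-sample manifest of the full study, with a ``group`` column.

    Sample ids are synthesized (``<dataset>-s####``); dataset ids and group
    sizes follow the published cohort table.
    """
    rows = []
    for group, datasets, tissue, cancer, n in COHORTS:
        for i in range(n):
            dataset = datasets[i % len(datasets)]
            rows.append(
                {
                    "sample_id": f"{dataset}-s{i:04d}",
                    "dataset_id": dataset,
                    "tissue_class": tissue,
                    "cancer_type": cancer,
                    "group": group,
                }
            )
    return pd.DataFrame(rows)


def group_total(manifest: pd.DataFrame, groups) -> int:
    if isinstance(groups, str):
        groups = (groups,)
    return int(manifest[manifest["group"].isin(groups)].shape[0])
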