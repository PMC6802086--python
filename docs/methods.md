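# Methods

## The problem and the model

Circulating tumor cells are rare (often single cells per mL of blood)
against ~10⁷ leukocytes per mL, so RNA markers for CTC detection must be
essentially silent in blood. The pipeline formalizes this as a two-sided
contrast on linear expression intensities: a probeset is a candidate
marker when its mean blood intensity does not exceed the chip background
and its fold change, mean(tumor)/mean(blood), is at least `min_fold`
(default 10). Folds are arithmetic-mean ratios on the linear scale
("average tumor over average blood"); a geometric-mean variant is
available via `SelectionConfig(fold_mean="geometric")`.

**Background.** "Chip background" has no closed-form definition on
microarrays; the package operationalizes it as a high quantile (default
0.99, linear-interpolation quantile) of the pooled blood value
distribution — a blood-derived ceiling under which expression is
indistinguishable from noise. For count platforms whose blood range is
known (log2 below 4), `background_level_override=4.0` fixes the ceiling
at 2⁴ instead.

**Probeset collapse.** Several probesets may report one gene; collapse
keeps the max-fold probeset per gene, with ties broken by lexicographic
probeset id so output is deterministic.

## Normalization

* **Quantile normalization** maps each sample's values onto the vector
  of row means of the column-sorted matrix, preserving within-sample
  ranks. Ties receive averaged ranks, i.e. the mean of the tied target
  quantiles, which makes the transform idempotent (verified to 1e-12).
  A single-sample matrix is returned unchanged with a warning.
* **Batch correction** across studies multiplies each study's log2
  values by `target/grand_mean`, where the target is the arithmetic mean
  of the study grand means. Multiplying the log2 values (rather than
  shifting them) is the literal reading of "scale factor correction" on
  averaged normalized data; it preserves within-study value ratios
  exactly. An additive-offset mode is exposed (`mode="additive"`) for
  users who prefer a location shift. Studies with non-positive grand
  means cannot be multiplicatively scaled and raise.
* **Pseudocounts** default to 0 for microarray-style intensities
  (strictly positive) and 1 for counts (so zeros map to log2 = 0).

## Counting-platform normalization

Lane factors follow the vendor-manual convention: for each control class
the factor is (arithmetic mean over lanes of the control geometric
means) / (lane's control geometric mean); a geometric-mean reference is
configurable. Positive-control scaling runs first (removing
lane-technical variation), housekeeping scaling second on the
positive-scaled counts (removing RNA-input variation) — the order is a
convention, fixed here as positive → housekeeping. Zeros are replaced by
1 before geometric means (configurable) to keep them finite. The
background threshold is mean + 2·SD of the normalized negative-control
counts, a common convention for this platform; targets below it are
flagged not-detected.

## Validation statistics

Boxplot summaries use linear-interpolation ("type 7") quartiles and
Tukey whiskers at 1.5·IQR clipped to observed values. Group comparisons
use the two-sample pooled-variance Student t (two-sided, α = 0.05),
matching the named test; Welch is available via `equal_var=False`.
p-values below 2.2e-16 are reported at that floor with a flag — the
floor is a reporting convention, not a computed value. No
multiple-testing correction is applied, matching the analysis design the
pipeline reproduces.

## Spike-in analysis

Concentrations in ng/µL are treated as masses in a unit volume, so a
10-ng/µL dilution contributes 10 ng against the 100-ng blood pool. The
mixture model is exact mass weighting:
`mix(g) = (m_s·cell(g) + m_b·blood(g)) / (m_s + m_b)`. With 10 pg RNA
per cell, the ladder 10, 1, 0.1, 0.01, 0.001 ng corresponds to 10³, 10²,
10, 1, 0.1 cell equivalents.

Detection pools all panel-gene log2 values within a dilution point and
compares them to unspiked blood replicates with the pooled t — with
technical duplicates there are too few replicates for per-gene testing
(a per-gene mode exists for larger designs). The limit of detection is
the smallest mass beginning an unbroken run of significant points up to
the largest mass, so an isolated low-mass fluke does not count.

**Why the smallest spikes are undetectable.** A 0.001-ng spike in 100 ng
of blood RNA is a 1e-5 mass fraction. With pure cell-line panel levels
around 2^9–2^10.5 against a blood background of 2^3, the mixture shifts
by only ~0.001–0.015 log2 units at the two smallest masses — far below
any realistic technical replicate noise — so the detection test cannot
(and should not) call them. Under the defaults, detection begins at
0.1 ng (10 cell equivalents); claims of single-cell-equivalent detection
from duplicate measurements are not supported by this model.

## Synthetic data generator

Defaults encode the study conditions end to end: discovery cohort sizes
417/41/401 (tumor/cell line/blood), 85 marker probesets → 80 genes (five
genes carry two probesets), marker folds uniform on [10, 300], blood
log2 background 3.0 ± 0.5 (keeping blood below 4), tumor panel levels
log2 8–10, cell lines 6–9, benign lesions 6.5–9, 17 batched datasets,
lane technical factors uniform on [0.7, 1.3]. The spike cell profile
defaults to log2 9–10.5: the pure-cell panel level implied by the
observed mixture interquartile levels (~4 at 1 ng, ~6 at 10 ng over a
100-ng pool at background 3).

Noise models: log-normal (sd 0.5 log2 biological, 0.15 technical) for
intensity data, Poisson for counts. Two deliberate idealizations:

* **Exact planted folds** — marker tumor rows are rescaled so the
  realized linear-mean ratio equals the drawn fold. Recovery tests then
  measure the selector, not sampling luck.
* **Flat spike blood pool** — the blood pool sets every panel gene to
  exactly 2^3 before technical noise, modeling a single physical RNA
  pool whose panel genes sit at the common noise floor. This keeps the
  pooled unpaired t exactly calibrated (type-I ≈ 0.05); shared
  gene-to-gene baseline variation would otherwise make it arbitrarily
  conservative.

What the generators do **not** emulate: probe-sequence effects, GC bias,
cross-hybridization, heavy-tailed outlier samples, correlated gene
modules, or tissue heterogeneity. Passing tests therefore demonstrate
the correctness and calibration of the computations under the stated
model, not performance on real cohorts.

Every generator is a pure function of its seeded config; equal seeds
give byte-identical files.

## Problem sizes

Unit tests run on scaled-down configs (300 genes, tens of samples);
recovery and calibration checks use the full default cohort sizes over
20 seeds and a 1000-replicate null simulation — a few seconds in total.
The acceptance script uses 5 seeds for recovery statistics and 1000 null
replicates.

## Known limitations

* The background quantile is a design choice with an override hook, not
  an estimate of the physical chip noise floor.
* Batch correction assumes comparable gene panels and near-equal true
  grand means across studies; biological composition differences leak
  into the factors.
* No upper fold bound is applied in selection (300 is the observed
  ceiling of the planted folds, not a filter).
* The pancreatic-CTC style comparison pools panel-gene values across
  genes and samples per group; per-gene pooling alternatives would give
  different p-values.
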