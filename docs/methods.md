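# Methods

This note documents the models and procedures implemented in `clonodyn`,
the parameter choices that matter, what the synthetic cohorts do and do not
emulate, and the numerical conventions used throughout.

## Clonotype calling and identity

A clonotype is the set of T cells sharing an identical TCR. Identity is
defined on the **nucleotide** CDR3 of the retained productive chains,
within a patient only — clonotype keys are prefixed with the patient
identifier and never compared across patients, because private nucleotide
rearrangements make cross-patient identity biologically meaningless at this
resolution (an amino-acid-level option exists for convergence analyses but
is off by default). Per barcode, productive TRA and TRB contigs are kept;
when a barcode carries more than one productive contig of the same chain,
only the highest-UMI contig is retained, with UMI ties broken by the
lexicographically smallest CDR3. This mirrors the dominant-chain convention
of droplet V(D)J callers and makes keys deterministic. Cells with no
productive TRA/TRB chain are left unkeyed (counted in the log, not
errors). Cell Ranger's own clonotype IDs can be declared authoritative
(`use_raw_ids=True`) instead of the derived signature; derived keys are the
default because they are reproducible from the contig table alone.

Timepoint A is pre-treatment; B and C are post-treatment. The dynamics
module pools B and C as "post" by default (testing each timepoint against A
separately is available via `post_timepoints`).

## Repertoire statistics

For clone frequencies `p_i`, Simpson clonality is `sqrt(Σ p_i²)` — the
convention common in immune-repertoire work: 1 for a monoclonal repertoire
and `sqrt(1/n)` under perfect evenness of `n` clones. Because several
related indices circulate (Simpson's `D = Σ p_i²`, inverse Simpson `1/D`),
all three are exposed under their own names; any published value can
therefore be matched to whichever convention produced it. Shared-clonotype
fraction is the fraction of clonotypes with ≥ 2 cells. Top-N clones are
ordered by size with ties broken by key order, for determinism.

## Clone dynamics classification

Each clonotype of a patient with both phases observed is tested with a
two-sided Fisher's exact test on
`[[n_pre, N_pre − n_pre], [n_post, N_post − n_post]]`, where `N` counts all
keyed cells of the phase. The two-sided p-value is the sum of
hypergeometric point probabilities not exceeding the observed one; tables
with a zero margin carry no information and get p = 1 by convention.
Classes at `α = 0.05` (raw, uncorrected — Benjamini–Hochberg within patient
is available but off by default, matching the use of a raw threshold for
this analysis): *expanded* if significant and frequency rose, *contracted*
if significant and frequency fell, otherwise *unchanged*. *Novel* is a
sub-flag of expanded requiring `n_pre = 0`: novelty is an observational
statement ("not detected pre-treatment"), so a planted low-frequency clone
that happens to draw zero pre-treatment cells is legitimately novel when it
expands.

Two calibration facts, both verified by the acceptance experiments: the
test is conservative under the null (false-positive rate well under α on
multinomially resampled repertoires), and power is strongly asymmetric —
ten-fold expansions from 0.5% are detected essentially always at 1000 cells
per phase, while contractions of clones that start at a handful of cells
are usually undetectable (the contracted state lands on the empty side of
the hypergeometric distribution). Cohort-level "contracted" counts are
therefore dominated by initially large clones; the per-group recovery
tables in `analysis/04` show this directly.

## Clonotype–phenotype integration

A clonotype belongs to every cell type that contains at least one of its
cells in a phase, per patient. The sharing matrix entry (i, j) is the
fraction of type-i clonotypes also seen in type j; the transition matrix
entry (i, j) is the fraction of pre-treatment type-i clonotypes found
post-treatment in type j. Both are computed per patient and aggregated by
summing numerators and denominators ("pooled"), which equals a
clonotype-count-weighted mean of per-patient fractions; an unweighted mean
mode exists because either aggregation is defensible and published heatmaps
rarely say which was used. Clonal dominance is operationalized as the
distribution of each cell's own clone size within its sample, summarized
per cell type (median, fraction of cells in clones of size ≥ 2 and ≥ 10).
CD4:CD8 ratios use a configurable celltype→lineage map.

## Signature scoring

The per-cell scorer is a single-sample rank-based enrichment statistic:
genes are ranked per cell by log-normalized expression (ties broken by gene
name, so scores are exactly reproducible), and the score is the signed
maximum deviation between the running sum over set members — weighted by
`|r|^τ`, `r` the descending rank statistic, `τ = 0.25` by default — and the
uniform running sum over non-members. At `τ = 0` this is the classical
unweighted Kolmogorov–Smirnov statistic, which is what the hand-enumerated
test cases pin down. Per-cell independence is the reason this scorer is the
default: scores never change when the cell population is subset, which the
pipeline relies on when comparing groups. The Gaussian-kernel variant
(per-gene kernel-CDF statistic across cells, bandwidth `std/4`, then the
same random walk with the max-deviation-from-zero convention) is provided
for fidelity to GSVA-style analyses, with the explicit caveat that its
scores are population-dependent.

Exhaustion and cytotoxicity gene memberships are configuration, shipped
with conventional surrogate markers (PDCD1, LAG3, HAVCR2, TIGIT, CTLA4 /
GZMB, PRF1, GNLY, NKG7): the curated lists used in the original analyses
are not printed anywhere, so absolute score values are not comparable —
only score *structure* (group separations, correlations) is.

Group comparisons use the two-sided Mann–Whitney U test: the exact U
distribution when both groups together have ≤ 20 tie-free observations,
the tie-corrected normal approximation otherwise; the rank-biserial
correlation `2U/(n₁n₂) − 1` is reported as the effect size. Gene–gene
association is Pearson correlation on log-normalized values, undefined
(reported missing) under zero variance.

## Expression-based CNV inference

Log-normalized expression (`log1p(count × 10⁴ / cell_total)`, natural log;
the scale is configurable) is centered gene-wise on a reference population
— healthy-donor monocytes by default, any barcode list accepted — and
clipped to ±3.0 to stop single outlier genes from masquerading as events.
Genes are ordered by start coordinate within each chromosome and smoothed
with a centered moving average of `floor(w/2)` genes on each side
(`w = 100`), truncated at chromosome ends and never crossing a boundary; a
trailing-window mode exists for replication attempts. A cell calls an arm
lost when its mean smoothed residual over the arm's genes is below
−0.15 (strictly), gained above +0.15; a sample carries the loss when at
least 50% of its evaluated cells do. The thresholds are declared defaults,
not derived quantities, and are echoed into every report.

One geometric consequence of the 100-gene window matters for arm-level
events on the 200-gene synthetic chromosomes: windows centered near the
p/q boundary mix lost and neutral genes, diluting a q-only event by tens of
percent. The generator therefore plants whole-chromosome loss (monosomy 7,
the classical lesion) by default, for which truncation at the chromosome
boundary removes the dilution entirely.

## Marker–response association

Patient-level 2×2 tables (marker present/absent × responder/non-responder)
are summarized by per-row response rates, the two-sided Pearson chi-square
without continuity correction (`χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`,
1 df), Fisher's exact p, and the cross-product odds ratio with Haldane's
+0.5 correction when any cell is zero. Displayed p-values are **floored**
(truncated) to two decimals — recomputing the published tables gives
0.0371 → "0.03" and 0.1187 → "0.11", consistent with truncation rather
than rounding — while full precision is always stored.

## The synthetic cohort generator

The generator's defaults encode the study design: 3 responders, 2 stable
disease, 3 non-responders, sampled at A/B/C, plus 2 healthy donors, and 800
cells per sample (the study's per-sample T-cell yield is on the order of a
thousand; every patient gets all three timepoints for regularity, slightly
more than the study's 22 samples). Disease compartments are 48% T cells,
35% blasts, and small B/monocyte/NK fractions; healthy marrow has no
blasts and a larger monocyte fraction (the CNV reference).

*Repertoire.* Healthy clone sizes are drawn directly from a discrete power
law with exponent 3.5 truncated at 16 cells — the bound is hard by
construction, mirroring the near-flat repertoires of healthy marrow.
Disease repertoires get a Zipf base law (exponent 1.0 over 300 clones,
configurable up to a 1200-cell maximum) and per-group expansion plans:
responders expand their dominant clones gently (fold 2.5) and a handful of
mid-rank clones strongly (fold 10) and receive novel clones at 2% post
frequency each; non-responders contract instead. Clone frequencies are
compositional, so planted mass added on one side necessarily depresses
everything else; the plans keep added and removed mass moderate so that
renormalization does not flood the classifier with spurious calls, and the
planted direction (responders: expanded > contracted; non-responders: the
reverse) is what the structural tests assert. Cells carry their clone's
"home" phenotype with fidelity 0.85; expanded and novel clones draw
cytotoxic CD8/MAIT homes, and ten persistent clones per patient switch
home from CD8 GZMK (pre) to CD8 CTL (post), planting the
phenotype-transition signal.

*Expression.* Counts are gamma-Poisson (negative binomial, dispersion 0.3 —
scRNA counts are overdispersed, and the rank-based scorer assumes nothing
stronger) around per-gene means: a lognormal baseline centered at 1.2
counts/gene over 2,000 genes on 10 pseudo-chromosomes of 200 genes (about
2,400 UMIs per cell, realistic for 5' data at this gene universe). Named
marker genes sit on chromosome 1 (never inside the planted lesion), are
near-silent outside their carrier cell types (off-state factor 0.08) and
boosted 2^1.5 inside them; three mitochondrial genes carry high baseline
means so that mitochondrial fractions are realistic. The exhaustion
program shifts PDCD1/LAG3/HAVCR2/TIGIT/CTLA4 in conventional T cells by a
per-(group, phase) log2 factor — responders start low and rise
post-treatment, non-responders start high. Arm loss multiplies the counts
of the lesion's genes by `2^(−shift)` (default shift 0.5, whole
chromosome 7) in the malignant cells of non-responder patients, so the
planted signal is recovered by the centering subtraction. Doublets (3% per
sample) are sums of two real cells' profiles, at least half forced T × B
with the B label and the T partner's TCR — making the TCR-in-non-T flag
100% sensitive to them by construction; low-quality cells (2%) have their
non-mitochondrial library scaled to 6%, putting them under both the
200-gene and the 15%-mitochondrial thresholds.

*What it does not emulate:* transcriptome-wide co-expression structure
(genes are conditionally independent given cell type), V(D)J sequence
realism (CDR3s are random nucleotide strings), batch effects, ambient RNA,
and clinical covariates. Passing recovery tests on these cohorts
demonstrates that the statistics recover what they are pointed at under
realistic sampling noise — not that the pipeline is robust to every
artefact of real droplet data.

A fixed seed makes the entire cohort, including all written files,
byte-for-byte reproducible; the CLI's aggregate report is likewise
byte-identical across reruns with one config and seed.

## Quality control

Genes detected in fewer than 3 cells are removed first; then cells with
fewer than 200 detected genes or a mitochondrial fraction strictly above
0.15. Doublet rules flag but never remove (removal is a pipeline option):
library-complexity outliers above the per-sample Tukey fence `Q3 + 3·IQR`
(the "aberrantly high gene count" notion is not quantified anywhere, so a
conservative scale-free fence is the declared default), co-expression of
≥ 2 markers from each of two mutually exclusive lineages, and TCR contigs
on barcodes annotated as non-T lineages.

## Problem sizes

The test suite runs the full pipeline on reduced cohorts (1 patient per
group, 120–300 cells per sample) and the calibration experiments at their
stated sizes (≥ 500 null clones at 1,500 cells per phase; 10 planted
expansions × 20 replicates at 1,000 cells per phase; 50 CNV patients at
100 cells each; 40 clonality seeds; 3 full cohorts for the direction
check). These sizes give stable Monte-Carlo estimates while keeping the
whole suite under a minute of compute; the acceptance script uses the same
sizes and the generator's full defaults for the cohort summary.
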