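# clonodyn

Paired single-cell RNA + TCR analysis of acute myeloid leukemia (AML) bone
marrow under PD-1-blockade therapy, packaged as a tested, reusable pipeline.

Relapsed/refractory AML patients treated with azacitidine + nivolumab show
very different T-cell behaviour depending on whether they respond: T-cell
receptor (TCR) repertoires expand — often through clones never seen before
treatment — in responders, and contract in non-responders, while loss of
chromosome 7/7q in the leukemic cells marks resistance to the combination.
`clonodyn` implements the quantitative core of that analysis for anyone
working with 10x-style paired 5' gene-expression + V(D)J data:

* **Clonotype calling** from `filtered_contig_annotations` tables: per
  barcode, productive TRA/TRB chains are retained (highest-UMI chain per
  locus, ties to the lexicographically smallest CDR3) and combined into a
  patient-scoped nucleotide clonotype key.
* **Repertoire structure**: clone-size distributions, shared-clonotype
  fraction, top-N clones, and Simpson clonality
  `C = sqrt(Σ_i p_i²)` (with Simpson diversity `D = Σ p_i²` and `1/D`
  available), where `p_i` is clone *i*'s frequency.
* **Clonotype dynamics**: for each clone, a two-sided Fisher's exact test on
  `[[n_pre, N_pre − n_pre], [n_post, N_post − n_post]]`; clones with
  `p < 0.05` are *expanded* or *contracted* by the direction of the
  frequency change, and expanded clones with `n_pre = 0` are *novel*.
* **Clonotype–phenotype integration**: clonal dominance per T-cell subset,
  top-3 clonotype composition, lineage sharing matrices, and pre→post
  phenotype transition matrices (e.g. CD8⁺ GZMK → CD8⁺ CTL), plus CD4:CD8
  ratios.
* **Per-cell signature scores**: a single-sample rank-based enrichment score
  (weighted Kolmogorov–Smirnov running sum, weights `|r|^τ`, max-deviation
  statistic; a Gaussian-kernel GSVA-style variant is included) for
  exhaustion/cytotoxicity/pathway gene sets, compared between groups with
  the two-sided Mann–Whitney U test.
* **Expression-based CNV calls**: log-normalized expression centered on a
  healthy-monocyte reference, clipped, smoothed by a 100-gene moving window
  along each chromosome, and thresholded into per-cell and per-sample
  arm-level loss/neutral/gain calls.
* **Marker–response association**: patient-level 2×2 tables (chr7/7q loss ×
  response) with response rates, the two-sided Pearson chi-square
  `χ² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))` (no continuity correction),
  Fisher's exact p, and a Haldane-corrected odds ratio.

The raw study data are controlled-access, so the package ships a first-class
**synthetic cohort generator** (`clonodyn.synthetic`) that emulates the study
design — 8 patients in three response groups sampled pre (A) and post (B, C)
treatment plus healthy donors, heavy-tailed clone sizes, response-dependent
expansion/contraction/novel-influx plans concentrated in cytotoxic CD8
phenotypes, marker programs on named genes, a planted chromosome-7 expression
down-shift in non-responders, and injected doublets and low-quality cells —
with full ground truth, so every stage has a parameter-recovery test.

## Worked example

The numbered drivers under `analysis/` run the whole story on the seeded
synthetic cohort (≈22k cells, 26 samples) and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_repertoire_clonality.py
python analysis/04_clonotype_dynamics.py
python analysis/08_marker_association.py
```

prints, among other things:

```
healthy: max clone 13, median clonality 0.059, shared fraction 0.124
disease: max clone 112, median clonality 0.214, shared fraction 0.465

NR: 2 expanded (1 novel), 17 contracted
SD: 15 expanded (10 novel), 14 contracted
responder: 37 expanded (31 novel), 27 contracted

icb_cohort: 10.5% vs 36.8% respond, chi2 p = 0.0371 (displayed 0.03)
azacitidine_cohort: 35.7% vs 17.6% respond, chi2 p = 0.1187 (displayed 0.11)
```

Reading it: healthy marrow repertoires are nearly flat (clonality ≈ 0.06, no
clone above 13 cells) while disease repertoires are dominated by large clones;
detected clonotype dynamics split by response group exactly as planted —
responders gain expanded and novel clones, non-responders mostly contract; and
the published patient-count tables reproduce the reported response rates and
chi-square p-values (10.5% vs 36.8%, p = 0.03 under the ICB combination; the
association disappears under azacitidine alone, p = 0.11).

The same stages are exposed as a CLI over a YAML config:

```bash
clonodyn --config run.yaml all        # simulate → qc → … → assoc + report.json
clonodyn --config run.yaml dynamics   # any single stage
```

Two runs with the same config and seed produce byte-identical reports.

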