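# mirlink

Integrative miRNA–mRNA regulatory network inference for endocrine-resistance
cell-line models, with a cross-cohort clinical biomarker evaluation and a
synthetic-data generator that plants recoverable ground truth under every
stage.

## The problem

Tamoxifen-resistant breast cancer sublines derived from a single parental
MCF-7 line show broad miRNA expression changes, but computational miRNA
target predictions are notoriously false-positive-prone. The approach
implemented here couples two expression readouts across the cell-line panel
— miRNA abundance measured as qPCR crossing points (Cp) and gene expression
as log2 microarray values — and keeps only predicted miRNA–target pairs
whose expression profiles move inversely across the panel.

The pipeline stages, each an importable module and a CLI subcommand:

1. **`qpcr_normalization`** — melting-curve QC (peak counting on −dF/dT) and
   a signal-dependent, non-linear normalization: per-sample offsets at 101
   quantile anchors against the across-sample mean quantile distribution,
   interpolated by a cubic smoothing spline of offset vs. Cp (GCV
   smoothing), with an isotonic correction keeping each sample map
   monotone.
2. **`smallrna_quant`** — 3′ running-sum quality trimming (Q20), a ≥15 nt
   length filter, exact-substring matching of unique reads against mature
   miRNA sequences (identical-sequence paralogs collapsed into groups,
   multi-mapping reads discarded), and median-of-ratios size factors.
3. **`differential_expression`** — per-contrast moderated two-sample t
   (pooled variance shrunk toward the across-feature mean with two
   pseudo-replicates of prior weight), Benjamini–Hochberg adjustment, the
   sign-consistency signature across ≥3 resistant lines, and the permissive
   |log2FC| ≥ 0.7 candidate filter.
4. **`target_integration`** — the core screen: replicate means per
   condition, Pearson correlation of miRNA Cp vs. gene expression profiles
   across the ≥4 conditions, negated so inverse regulation appears as
   r → −1; a pair becomes a *predicted functional target* iff r ≤ −0.8 and
   ≥2 of 6 target predictors support it.
5. **`enrichment_stats`** — two-sided Wilcoxon rank-sum comparison of
   target vs. non-target fold changes reported as signed log10 p (negative
   when targets rank lower), odds ratios with Fisher tail-doubling p for
   regulation accounting, and a generic hypergeometric over-representation
   test.
6. **`outcome_classification`** — ridge-stabilized logistic regression of
   recurrence on miRNA marker combinations, fit per cohort and tested on
   all cohorts, summarized by trapezoid AUC (equal to the tie-corrected
   Mann–Whitney U over n₁n₀).
7. **`synthetic_data`** — generates all five input kinds (Cp matrix,
   expression matrix, FASTQ + FASTA, prediction table, patient cohorts)
   from a planted regulatory network with inverse coupling, smooth
   per-sample Cp bias, decoy predictions and logistic outcome effects.
8. **`formats_io`** — TSV/FASTA/FASTQ/JSON/YAML readers and writers plus
   the `mirlink` CLI.

## Worked example

The bundled dataset `mirlink.datasets.resistant_line_screen()` is the
published 22 × 3 log2 fold-change matrix of miRNAs significantly altered
(adjusted p < 0.05) in all three resistant sublines:

```python
>>> from mirlink import consistent_signature, select_candidates
>>> from mirlink.datasets import resistant_line_de_results
>>> sig = consistent_signature(resistant_line_de_results())
>>> len(sig.up), len(sig.down)
(14, 8)
>>> len(select_candidates(resistant_line_de_results(), lfc_threshold=0.7))
22
```

14 miRNAs are consistently upregulated and 8 consistently downregulated;
every one of the 22 passes the |log2FC| ≥ 0.7 candidate filter in at least
one subline (the extreme value is −6.16 for miR-135a in TamR4).

An end-to-end run on simulated data:

```console
$ mirlink all --seed 1 --outdir run1
wrote 21 files to run1/inputs
2 of 20 assays flagged
replicate SEM reduction: 48.9%
quantified 12 samples x 29 groups
...
158 predicted functional target pairs (28 miRNAs, 28 candidates)
```

with `run1/report.json` reporting, among others,

```json
"edge_recovery": {"precision": 0.829, "recall": 0.873, "n_true_edges": 150}
```

i.e. the inverse-correlation screen recovers the planted 150-edge network at
~83 % precision and ~87 % recall after normalization; run on the raw
(consensus-centered-bias) matrices the defaults give ≥ 80 % on both across
seeds. The "2 of 20 assays flagged" line is the melting-curve QC finding
exactly the simulated two-product assays, and the SEM reduction quantifies
how much replicate scatter the quantile-spline normalization removed.

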