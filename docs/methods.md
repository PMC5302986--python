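# Methods

This note documents the models, defaults and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## Study design assumed throughout

One parental (tamoxifen-sensitive) condition plus at least three
independently derived resistant conditions, each profiled in biological
triplicate on (a) a miRNA qPCR panel reporting crossing points (Cp, PCR
cycles; lower Cp = more template) and (b) a gene expression array reporting
RMA-style log2 values. Contrasts are always resistant vs. parental.

## qPCR normalization

**Melting-curve QC.** Fluorescence is smoothed by a 3-point centered moving
average, differentiated against temperature, and peaks of −dF/dT are
counted with `scipy.signal.find_peaks`; a peak counts only if its
prominence reaches 20 % of the tallest peak's height, so ripples on a
dominant melt transition are ignored. Assays with >1 peak amplify more
than one product and should be excluded. The smoothing window and
prominence fraction are package choices — melt QC conventions vary and
no standard parameters exist; both are exposed as arguments.

**Quantile-spline normalization.** qPCR plates suffer *signal-dependent*
distortions: the error a sample incurs depends on where on the Cp scale a
feature sits, so a location/scale correction is insufficient. For each
sample, offsets are computed at 101 quantile anchors as (target quantile −
sample quantile), where the target distribution is the across-sample mean
of per-sample quantiles (a symmetric choice; any explicit target vector can
be supplied instead). A cubic smoothing spline of offset vs. Cp
(`make_smoothing_spline`, smoothing parameter chosen by generalized
cross-validation) turns the anchor offsets into a smooth correction
function, and the implied map `x + offset(x)` is projected onto
non-decreasing functions by isotonic regression on a 256-point grid, which
guarantees within-sample rank preservation. Outside the fitted range the
boundary offset is applied (constant extrapolation, slope 1, still
monotone). Undetected assays (`NA`) pass through untouched.

Like all quantile-matching methods this assumes the samples share an
underlying distribution; with very small panels where *every* feature
genuinely shifts, quantile matching absorbs real signal (see "recovery
surface" below).

**SEM reduction.** The before/after quality metric averages the replicate
standard error of the mean over all (feature, condition) cells with ≥2
detected replicates and reports `100·(1 − after/before)`. Its value is
dataset-specific; only its sign and monotone growth with planted bias
amplitude are contractual.

## Small-RNA quantification

Reads are adapter-stripped (leftmost 3′ suffix matching a prefix of the
configured adapter, minimum overlap 3 nt), then 3′ quality-trimmed by the
running-sum rule at Q20 (cut at the position maximizing the accumulated
quality deficit from the 3′ end — the BWA convention; no algorithm is
standard for this step, so the choice is documented rather than inherited).
Reads shorter than 15 nt after trimming are dropped. Surviving reads are
collapsed to unique sequences with copy numbers before matching.

Matching is exact: a read is assigned to a reference entry iff one sequence
is a substring of the other (no mismatches, no gaps). Containment in either
direction accommodates reads shorter or longer than the mature sequence
after trimming. Mature miRNAs with byte-identical sequences (e.g. paralog
families) are collapsed into *sequence groups* before matching; without
this, a literal per-id multi-map rule would discard every read hitting such
a family, zeroing out real miRNAs. Reads matching more than one distinct
group are discarded and tallied; per sample,
`assigned + multi-mapped + unmatched = unique reads` always holds.

Size factors are median-of-ratios: the reference is the per-feature
geometric mean over samples (features with any zero excluded), each
sample's factor is the median ratio of its counts to the reference.

## Differential expression

A two-sample t statistic per feature with the pooled variance shrunk toward
the across-feature mean variance: `s²_mod = (d₀·s̄² + d·s²)/(d₀ + d)` with a
fixed prior weight of d₀ = 2 pseudo-replicates. This is a deliberately
light-weight form of empirical-Bayes moderation — no prior-df estimation,
no variance trend. The p-value uses a moment-matched reference
distribution: `s²_mod` has the spread of a scaled χ² with `(d₀+d)²/d`
degrees of freedom (for triplicates, 9 rather than 6), and a t distribution
with that df calibrates the null rejection rate at the nominal level
(verified by simulation in the test suite; using d₀+d df is measurably
conservative).

Cp contrasts negate the mean difference so a positive log2FC always means
higher abundance in the resistant condition. Features with <2 detected
replicates on either side are skipped and listed. Count matrices are tested
on `log2(normalized count + 0.5)` with the fold change reported from
normalized group means; all-zero features are untested.

BH adjustment is the exact step-up rule, implemented in-repo and checked
against both a brute-force oracle and statsmodels.

**Consistency signature.** A feature enters the signature iff it is
significant (adjusted p < 0.05) with the same fold-change sign in *every*
contrast; mixed-sign features are excluded. The bundled published screen
(22 miRNAs × 3 resistant lines) is the worked example: 14 up, 8 down. For
externally reported tables where only the significance *call* is published,
`DEResult.from_reported` encodes the call with padj = 0.

**Candidate filter.** |log2FC| ≥ 0.7 in ≥1 contrast, no p-value condition —
deliberately permissive, since the downstream correlation screen does the
filtering. Threshold comparisons are inclusive at the printed values
everywhere (≥ 0.7, ≤ −0.8, ≥ 2).

## Target integration

Replicates are averaged to one value per condition; a (feature, condition)
mean over fewer than two detected replicates marks the feature incomplete
and removes it from correlation (the detection limit handling is a package
choice; the assay chemistry does not define one).

The screen correlates each candidate miRNA's Cp profile with each gene's
expression profile across the shared conditions and negates the
coefficient: because Cp is inversely proportional to abundance and a
repressing miRNA is expected to vary inversely with its targets, a genuine
repressive edge yields positive Pearson(Cp, expression), hence negated
r → −1. One correlation matrix is computed jointly over all conditions
(a per-resistant-line mode is not offered a fidelity claim; the joint
4-condition design is the implemented reading).

With only 4 condition means, r ≤ −0.8 is a *screening heuristic*, not a
calibrated test — under independence, |r| ≥ 0.8 occurs in roughly a fifth
of random pairs — which is exactly why the multi-predictor support gate
(≥2 of 6 tools) is load-bearing. The module refuses to correlate fewer
than 3 shared conditions; zero-variance profiles yield undefined entries,
dropped and tallied.

**Regulation coverage.** The fraction of differentially expressed genes
that are functional targets of ≥1 differentially expressed miRNA, plus the
2×2 table (DE vs. not) × (targeted vs. not) over the gene universe fed to
the odds-ratio test. The contingency construction is a declared choice;
"accounted for" has no unique formalization.

## Enrichment statistics

Per miRNA, a two-sided Wilcoxon rank-sum test of its functional targets'
fold changes against all non-targets — including predicted-but-not-
functional targets, which deliberately remain in the background. Exact
enumeration when both sides have ≤10 members, otherwise the normal
approximation with mid-rank tie correction and continuity correction. The
result is reported as signed log10 p: negative when targets rank *lower*
(more downregulated) than the background, positive otherwise — so coherent
repression by an upregulated miRNA appears negative. The sign is computed
from the targets' rank sum vs. its null expectation; BH runs across
miRNAs; miRNAs with <3 measurable targets are flagged low-power. Tests are
run per contrast.

Odds ratios use the Haldane correction (add 0.5 to every cell when any is
zero); the two-sided Fisher p doubles the smaller hypergeometric tail of
the observed cell (capped at 1). The over-representation test is a plain
one-sided hypergeometric per named gene set with BH across sets — generic
plumbing, with no pathway database shipped.

## Outcome classification

Logistic regression of recurrence on a miRNA combination, fit by
Newton/IRLS with step halving, a ridge penalty of 1e-6 on the coefficients
(not the intercept) as a numerical guard against separation, convergence at
penalized gradient norm < 1e-8 or 500 iterations. Features are
standardized with the *fit cohort's* mean and SD, applied unchanged to test
cohorts: cohorts profiled in different batches share no scale, and learning
scaling from a test cohort would leak. Every (fit cohort, combo) model is
evaluated on every cohort; fit = test entries are flagged training
performance. ROC curves sweep the unique scores with ties grouped; the
trapezoid AUC then equals the tie-corrected Mann–Whitney U over n₁n₀
(a test-suite invariant), and is invariant under monotone score transforms.
Combination search is exhaustive over the listed markers up to size 3.

## The synthetic-data generator

The generator's defaults are the assumed study conditions: 30 panel miRNAs,
200 genes, 150 regulatory edges, 4 conditions × 3 replicates, replicate
noise 0.2 Cp and 0.2 log2 units (typical scatter for LNA qPCR panels and
RMA-summarized arrays), condition shifts of 1–3 log2 units (the magnitude
range of the published signature), repression strengths U(0.5, 1.5), Cp
affine in log2 abundance (slope 1, intercept 35), and cohorts of 52/60/40
patients at ~50 % recurrence prevalence.

Mechanics worth knowing:

* **Identifiable network by default.** Each target gene is regulated by at
  most one miRNA unless `shared_targets=True`. A pairwise correlation
  screen cannot attribute a gene driven by two comparable regulators to
  either one (two independent regulator profiles dilute r to ≈ 0.71,
  below the 0.8 gate), so an identifiable planted network is the honest
  default for measuring what the screen can do; the shared-target mode
  exists to demonstrate precisely that failure.
* **Consensus-centered bias.** Per-sample Cp biases are low-order
  polynomials of the signal, centered across samples and scaled so the
  largest distortion equals the configured amplitude. Centering makes
  "recover the planted bias" well-posed — quantile normalization can only
  correct toward the panel consensus, never toward an absolute truth. The
  generator returns the same draw with and without bias (`cp`/`cp_nobias`,
  identical noise), so a normalization can be scored exactly.
* **Decoy predictions.** Every true edge gets ≥2 supporting predictors (no
  planted edge dies at the support gate); decoys enter at rate 0.05 per
  non-edge pair with truncated-geometric support (70 % have support 1),
  so some decoys pass the gate and the correlation filter must reject them.
* **Reads.** Drawn multinomially per sample proportional to linear-scale
  abundance; without an adapter every read is exactly its reference
  sequence at Q40. A configurable fraction of reference entries are
  byte-identical paralogs to exercise the sequence-group collapse.
* **Cohorts.** Marker expression is standard normal plus a per-(cohort,
  miRNA) technical batch shift (SD 0.25). Recurrence is drawn from
  `expit(logit(prevalence) + Σβᵢxᵢ)` on the *biological* signal — batch
  shifts are measured but not prognostic, keeping class balance calibrated
  and making fit-cohort standardization meaningful.

What the generator does **not** emulate: sequencing errors and isomiRs,
amplification-efficiency differences between assays, missing-not-at-random
Cp dropout, correlated gene programs (genes are conditionally independent
given their regulator), real cohort censoring or covariates. Passing tests
on this generator therefore show the *methods* behave as specified under
their own assumptions, not that the biological conclusions of any
particular dataset would reproduce.

## Recovery surface and problem sizes

With the default generator settings the full screen (candidate filter →
joint correlation on raw condition means → support gate) recovers the
planted network at ≥ 80 % precision and recall; across 20 seeds the
observed minima were 0.815 (precision) and 0.933 (recall). The screen is
run on raw condition means: the planted bias is consensus-centered and
largely averages out of condition means, whereas quantile normalization on
a 30-feature panel in which *every* feature shifts absorbs real signal and
costs recall — a known small-panel limitation of quantile matching, not of
the spline fit. Normalization recovery is instead demonstrated where its
assumption holds (200 features, no condition shifts, planted amplitude
1.5 Cp): offsets recovered within 0.1 Cp RMS at the anchors, and
renormalization offsets below 0.05 Cp (idempotence).

Test and verification problem sizes (chosen to make sampling bands tight
while keeping the default suite fast): 1,000-feature null matrices and 500
rank-sum replicates for type-I error (3σ binomial bands around 0.05),
n = 2,000 for logistic coefficient recovery (±0.2), 1,000 random instances
for the AUC/U and BH oracle equivalences, and exhaustive enumeration up to
8 observations per side for the exact rank-sum oracle.

## Known limitations

* The moderated t uses a fixed prior weight, not estimated prior df; it is
  calibrated under roughly homogeneous feature variances and will not
  match limma/DESeq numerics feature-for-feature.
* n = 4 correlations are screening-grade only (documented above); no
  p-value is attached to r.
* The exact rank-sum enumeration ignores ties (exact mode is used only for
  ≤10-per-side, where the continuous fold changes make ties measure-zero).
* The CLI `all` chain normalizes before integrating, which is correct for
  realistic panel sizes but, per the small-panel caveat above, slightly
  conservative on the 30-feature default simulation.
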