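# Methods

This note documents the statistical procedures, the synthetic-study
generator, the numerical conventions and the design choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. CNA discretization and anchor integration

aCGH cohorts arrive either pre-called (loss −1 / neutral 0 / gain +1) or as
log2 ratios. Ratios are discretized by fixed thresholds, default ±0.2 on
the log2 scale, with **strict** inequalities: a value exactly at a cutoff
is neutral. The threshold caller deliberately replaces mixture-model
calling — the pipeline's downstream stages consume calls, not the calling
model, and pre-called input is the first-class path.

Different cohorts use different probe sets, so probe-level calls are not
directly comparable. We place all cohorts on a common grid of **anchors**:
the sorted union of every probe's start and end position, per chromosome.
A probe covers an anchor under half-open containment (`start ≤ pos < end`);
a covered anchor inherits the probe's call vector, an uncovered one gets a
missing vector. Anchors missing from more than one dataset are dropped. If
one dataset has two probes covering the same anchor, the smaller-span probe
wins (ties to the leftmost start) — deterministic, and favors resolution.

**Permutation test.** Per anchor we test the pooled gain count (and,
separately, loss count) against a null in which each sample's calls are
shuffled independently across that sample's informative anchors. This null
preserves each sample's aberration burden, the dominant confounder: a
genome-unstable sample inflates every anchor equally under the null.
Implementation note: at any fixed anchor the shuffled call of sample *s*
is uniform over its informative calls, so per-anchor null counts are
simulated directly from these per-sample marginals (grouped by the anchors'
missing-sample pattern). This is identical in distribution to materialised
permutations — the test suite checks it against exhaustive enumeration on
a 3-sample toy — and makes 10^6 permutations feasible. Empirical p-values
use the add-one convention, p = (b + 1)/(n_perm + 1), so p = 0 is
impossible. Default n_perm is 10^4 in the library pipeline and 10^6 at the
CLI.

Runs of same-direction significant anchors (p < 0.05) merge into aberrant
regions when inter-anchor gaps are ≤ `max_gap` (default 500 kb, about five
probe lengths at the synthetic probe density — large enough to bridge
probe-boundary jitter, small enough not to fuse separate planted regions).
An anchor significant in both directions joins the side with the smaller p.

## 2. Differential ranking and robust rank aggregation

Per cohort, features are scored by Welch's two-sample t statistic
(tumor vs normal), Benjamini–Hochberg adjusted, split by the sign of the
mean difference (non-positive → "down", so a tumor≡normal feature lands
last in the down list with adjusted p = 1) and ranked by adjusted p, ties
broken by |mean difference| then id. The moderated-t machinery of
microarray pipelines is intentionally not reproduced: the meta-analysis
consumes only ranks, which are insensitive to the exact per-cohort
statistic.

Aggregation scores a feature by order statistics of uniforms. With
normalized ranks r(1) ≤ … ≤ r(n) over the n lists where the feature is
measured,

    beta_k = P(at least k of n U(0,1) ≤ r(k)) = Σ_{j=k}^{n} C(n,j) r(k)^j (1−r(k))^{n−j}
    rho    = min_k beta_k
    p      = min(1, n · rho)        (Bonferroni over the n order statistics)

Features measured but not listed receive the worst normalized rank (1):
dropping them would bias toward features reported by few studies. The
leave-one-out (LOO) correction repeats the aggregation N times, excluding
each list once, and averages the N p-values; a round in which the feature
has no measured list contributes p = 1. A feature significant in both
directions keeps the direction with the smaller LOO p; exact ties among
significant features are excluded and logged.

**Normalization denominator.** Expression cohorts declare their measured
universe, so ranks are normalized per list. For published miRNA lists the
platform is usually unknown and two denominators are defensible: the
study's platform size or the union of all reported miRNAs. We normalize by
the declared platform size (the generator declares the full miRNA
universe; the CLI exposes `--universe-size`). The union denominator is far
smaller than any real platform, which inflates normalized ranks and costs
so much power that a miRNA reported by 5 of 9 studies — the typical case
at an 80% detection rate — cannot reach p < 0.05. Union normalization
remains available as an option.

Significance cutoffs follow the study design: LOO-corrected p < 0.01 for
genes, p < 0.05 for miRNAs.

## 3. Paradox classification and sample-wise validation

Deregulated genes are assigned to aberrant regions by ≥1 bp overlap; a gene
overlapping both directions takes the larger total overlap (exact ties
dropped and logged). The 2×2 association between DE direction (up/down) and
region direction (gain/loss) is tested by Pearson chi-square, 1 df, no
continuity correction; a zero marginal raises an error advising an exact
test. A gene is **paradoxical** iff its DE direction times its region
direction is −1.

Validation uses a matched cohort with per-sample expression and per-gene
log2 copy number. Tumor expression is z-scored against the normal-sample
distribution (sample sd, ddof 1; genes with constant normals become
missing) — the reference population is a choice; all-sample
standardization would be the alternative, but normals are the natural
anchor when they exist. Per gene, over samples with both values present:

* paradoxical event: z beyond ±1.647 on the gene's DE side **and** log2
  CNA beyond the 0.2 cutoff on the opposite (region) side;
* regular event: same deregulation with the CNA on the DE side.

The cutoff 1.647 is kept exactly as conventionally printed (not 1.645).
The test statistic is T = freq_paradoxical − freq_regular, and the null
permutes the gene's CNA vector against its z vector. T depends on a
permutation only through how many deregulated samples receive region-side
and DE-side CNA labels, so the null is drawn exactly from the
corresponding multivariate hypergeometric law instead of materialising
shuffles (verified against explicit enumeration on a 5-sample toy). A gene
is validated when p < 1e-4 (add-one empirical p; n_rand defaults to 10^5
so the floor 1/(n_rand+1) lies below the cutoff) and the excess is
positive.

## 4. miRNA association

* **Target overlap**: hypergeometric test of the overlap between validated
  paradoxical genes and genes targeted by the validated deregulated
  miRNAs, population = all genes entering the rank aggregation. Tails are
  **strict**, P(X > observed): recomputing the published worked example
  (population 15,323; 7,836 targeted; 70 drawn; 46 overlapping) gives
  4.83e-3 under the strict tail — matching the printed 4.8e-3 — versus
  9.6e-3 inclusive.
* **Partial correlation**: first-order Pearson partial correlation of
  miRNA and gene expression across tumor samples, controlling for the
  gene's copy number, r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²));
  undefined when a controlling correlation is ±1 (flagged missing). The
  continuous log2 value is used as the control when available, else the
  discrete call.
* **Empirical pair null**: the same measure over n_null (default 10^4)
  miRNA:gene pairs drawn uniformly with replacement from the full
  universes, excluding the tested pairs; two-sided p =
  min(1, 2·(min(lower, upper)+1)/(n_null+1)); significant at p < 0.05.
* **Explanatory**: a significant pair whose correlation sign equals the
  product of the two deregulation directions (repression-consistent);
  r = 0 is never explanatory.
* **Multiple correlation**: C = √(cᵀR⁻¹c) with c the gene's correlations
  to each miRNA and R the miRNA×miRNA correlation matrix — equivalently
  the correlation between the gene and its best linear prediction from the
  panel (the test suite checks this equivalence to 1e-8). If R is singular
  or C² leaves [0,1] by more than 1e-8, the least-squares pseudo-solution
  is used and the result clipped, with a condition-number warning.
  Percentiles are the fraction of a genome-wide background strictly below
  the gene's C; enrichment of paradoxical genes in the top 5% is tested
  hypergeometrically (successes = ⌊0.05·background⌋, strict tail).

## 5. The synthetic study

The generator emulates the multi-cohort design the pipeline targets, at
desk scale. Defaults: 2,000 genes on 5 chromosomes of 10 Mb; 8 aberrant
regions (alternating gain/loss, each ~1.25 Mb ≈ 50 genes, in
non-overlapping chromosome slots); 3 aCGH cohorts of 60 tumors on
independently jittered ~100 kb probe tilings; per-region aberration
frequency 0.40 (the top of the commonly reported 0.07–0.45 per-region
range, so planted regions are recurrent) over a background rate of 0.01;
4 expression cohorts of 60 tumors / 15 normals with 5% per-cohort gene
dropout; 40 miRNAs of which 10 are deregulated (half up) with a ±1.5 log2
shift and 0.5 per-sample spread; 9 miRNA studies at 80% detection with
0–4 false positives each; a matched validation cohort of 150 tumors / 40
normals with log2 ratios around class means (−0.5, 0, +0.58) ± 0.1; 60
planted paradox genes with 1–2 regulator miRNAs each.

Tumor expression is generated on the log scale as

    x[g,s] = baseline_g + alpha·call[g,s]
             − Σ_m beta[g,m]·dmir[m,s]·(1 + kappa·ab[g,s]) + N(0, sigma)

with alpha = 0.5 (dosage), sigma = 0.5, beta = 1.0 for ordinary miRNA
targets, and dmir the per-sample deviation of a deregulated miRNA from its
baseline (shared with the miRNA expression matrix, which is what makes the
miRNA:gene correlations real rather than assumed).

**Clonal compensation (kappa).** For planted paradox genes the repression
carries an interaction: it is amplified by a factor (1 + kappa), default
kappa = 4, in samples that carry the gene's region aberration. This
encodes the biological claim the paradox rests on — the tumor clone that
acquired the gain still needs the gene silenced, so the epigenetic
counter-regulation is strongest exactly where the dosage pushes hardest.
It is also statistically necessary: without the interaction, deregulation
anti-correlates with the opposite-direction CNA within a gene (the dosage
term is the only coupling), and no paradox gene could pass a sample-wise
co-occurrence test — under a repression-independent-of-CNA model the
validation null is actually favored. Per paradox gene, beta is solved so
the expected tumor-vs-normal shift equals 3 noise-SDs opposite to the
region direction (the floor for a well-posed paradox is 2).

Decoy targets of deregulated miRNAs (8 per miRNA) are placed outside
aberrant regions: they become strongly deregulated genes that must *not*
be classified paradoxical, exercising the region-overlap logic, and they
populate the background of the multiple-correlation percentile with
genuinely miRNA-correlated genes.

What the generator does **not** emulate: probe-level microarray noise
(expression is simulated directly at the summarized log scale),
segmentation artifacts (calls are generated per probe/gene), tumor purity
gradients, batch effects, and correlated miRNA co-regulation programs.
Passing recovery tests therefore demonstrate the pipeline's logic and
calibration under its stated model, not robustness to those real-data
pathologies.

## 6. Determinism and problem sizes

Every generator and every Monte-Carlo test draws from a named substream of
a single seed (numpy `SeedSequence`); reports list all derived seeds, and
reruns are bit-identical. The default problem sizes (above, with n_perm =
10^4, n_rand = 10^5, n_null = 10^4 in the library pipeline) complete a
full run in a few seconds; the test suite's calibration checks use 10^3
independent null replicates per test with proportionally smaller
Monte-Carlo sizes, chosen so empirical p-value resolution stays well below
the levels being checked.

## 7. Known limitations

* The permutation null for anchors and the randomization scheme for
  sample-wise validation are defensible choices among several; both are
  documented above and alternatives (global label shuffle; all-sample
  z-standardization) are intentionally configurable or noted.
* The region-merging rule (gap-bounded runs of significant anchors) is a
  pragmatic reconstruction; arm-level reporting conventions differ.
* The chi-square stage requires all four margins populated; heavily
  one-sided designs need an exact test instead.
* miRNA name harmonization is lowercase + arm-suffix stripping only; full
  alias resolution against a registry is out of scope.
* With fewer than 4 input lists the LOO correction is harsh (each round
  keeps ≤ 2 lists); consensus calls from 2–3 cohorts should use the
  uncorrected aggregate p or a relaxed alpha.
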