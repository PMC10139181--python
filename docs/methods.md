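# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Site calling

Each cytosine in a sample carries counts (m, u) of methylated and
unmethylated reads. The null model is that an observed "methylated" base
arises by chance with probability ½, so the one-tailed p-value is the exact
binomial tail P(X ≥ m | n = m+u, ½), computed via the regularized
incomplete beta function (verified against rational-arithmetic enumeration
to 10⁻¹² for all depths ≤ 25). A *true methylated site* requires depth ≥ 5
and Benjamini–Hochberg q ≤ 0.01.

Choices:

* **Test direction.** One-tailed toward excess methylation — the only
  direction consistent with *calling* methylated sites.
* **BH family.** Per sample, over all sites at or above the depth floor,
  contexts pooled; a pooled-across-samples mode
  (`call_true_methylated_pooled`) is provided. Note a subtlety: the called
  set is monotone in the FDR cutoff, but *not* in `min_depth` — raising
  the floor removes mostly large-p shallow sites from the BH family, which
  can lower the q-values of the remaining deep sites. The test suite
  asserts monotonicity only where it mathematically holds.
* **Null probability.** p₀ = 0.5 exactly; a `p0` argument allows a
  conversion-failure-based null (e.g. p₀ ≈ 0.006) for users who prefer
  testing against chemistry error instead of the coin-flip null.
* Zero-depth sites are parsed and retained but never tested and never
  enter summaries.

The conversion rate is 100·Σu/Σ(m+u) over control-chromosome sites only.
Sample summaries use ordinary least squares for the per-chromosome count
vs chromosome-size regression and Pearson correlation on shared called
sites; identical constant vectors are reported as r = 1 rather than
undefined.

## Annotation

Coordinates are 0-based half-open internally; files are converted at the
boundary (GTF 1-based inclusive, BED 0-based half-open). The eight feature
classes are CpG islands, CGI shores, promoters, 5′/3′ UTRs, exons, introns
and repeats.

* **Promoter** := 1000 bp upstream of the TSS through the TSS base,
  strand-aware. The 1 kb width matches the pipeline's gene-association
  convention.
* **Shores** := 2000 bp flanking each CGI, clipped at neighbouring CGIs
  and chromosome ends (community convention).
* **Gene association**: a query is linked to every gene whose span
  extended by 1 kb both ways intersects it; the boundary is inclusive at
  exactly 1000 bp and exclusive at 1001 bp.
* **Multi-label assignment**: a query returns *all* intersected classes (a
  region spanning an exon–intron junction counts under both), because the
  integration table demonstrably lists one DMR under several regions. A
  priority mode (promoter > utr5 > exon > utr3 > intron > repeat > shore >
  cgi) yields single labels for summaries that need them.
* **Feature methylation** is the unweighted mean of per-site fractions
  over tested sites (depth ≥ 5) in the feature, ×100; whether published
  feature percentages weight sites by coverage is generally unstated, so
  the unweighted choice is recorded here and in output metadata. Features
  containing no tested site give a missing value, never zero.

Stage statistics: Shapiro–Wilk per (feature, stage) variable (skipped with
a warning below 3 observations or for constant input), pairwise t tests
and Kruskal–Wallis + Dunn post-hoc z (Bonferroni-adjusted, tie-corrected
rank variance) across stages, one-way ANOVA across features. Dunn's
statistic is implemented directly from joint ranks (verified against hand
computation) since no installed package provides it.

## DMR detection

The two-group test is a smoothed beta-binomial Wald test with
empirical-Bayes dispersion shrinkage, in the spirit of the dispersion-
shrinkage region callers used for bisulfite data, re-implemented and
simplified so that every step is visible:

1. **Alignment.** Sites present with depth ≥ 1 in every sample of both
   groups, per context; CG, CHG and CHH streams never mix. "True
   methylated" calls are *not* a prerequisite — all covered sites are
   tested (the descriptive site calls serve the summaries), with a config
   flag for the restricted mode.
2. **Smoothing.** Coverage-weighted moving average over ±250 bp
   (window = 500 bp); isolated sites pass through unchanged.
3. **Dispersion.** The beta-binomial with mean μ and dispersion
   φ ∈ (0,1) has Var(X) = nμ(1−μ)(1+(n−1)φ); φ = 0 degenerates to the
   binomial. Per site, a method-of-moments estimate from replicate
   residuals around the group means (inflated by k/(k−g) for the g fitted
   means) is shrunk on the log scale toward a genome-wide prior with
   weight λ = D₀/(D₀ + depth), D₀ = 2000 depth units. The prior is the
   *pooled* moment estimate (numerators and denominators summed over
   sites) rather than a mean of per-site logs: with 6 replicates the
   per-site estimates frequently clip at zero and a mean of their logs
   collapses, which in testing under-estimated variances badly enough to
   produce false regions. Per-site estimates are floored at prior/20
   before the log average. Clip range [10⁻⁶, 0.999].
4. **Wald test.** w = (μ̂₁−μ̂₂)/√(V₁+V₂) with
   Vg = μ̂g(1−μ̂g)·Σᵢ nᵢ(1+(nᵢ−1)φ̃)/(Σᵢ nᵢ)², the sum running over
   samples and window sites — the exact variance of the coverage-weighted
   window mean under the model, treating window sites as independent
   observations of a common mean. μ̂g(1−μ̂g) is floored at the 1/(N+2)
   add-one scale so saturated windows keep a nonzero variance. Two-sided
   normal p. On null beta-binomial data (μ = 0.3, φ = 0.05, depth 30,
   3 vs 3) the raw p < 0.05 fraction sits at ≈ 0.09 — slightly hot, as
   expected for a Wald test at 3 replicates, and inside the accepted
   calibration band.
5. **Regions.** Maximal runs of significant (p < 10⁻⁵), sign-consistent
   sites with inter-site gaps ≤ 100 bp. Because smoothing lets sites just
   outside a true region borrow its signal, boundaries are refined by a
   changepoint rule: over the run's members, the maximum-sum contiguous
   segment (Kadane) of direction·raw_diff − τ, with τ = 0.5 × the run's
   effect estimate (the larger of the smoothed plateau and the median raw
   difference over significant sites — the plateau alone is diluted when
   the region is shorter than the window). A surviving run is a DMR when
   span ≥ 50 bp, ≥ 3 tested sites, ≥ 50% of members significant. Region
   means, the difference, and the methylation
   log2FC = log₂((μ₁+ε)/(μ₂+ε)) (ε = 0.01, configurable) come from raw
   unsmoothed pooled counts; areaStat is Σw over members. Coordinates are
   reported 1-based inclusive; BED export converts.

Measured behaviour at defaults (3 vs 3, depth 30, Δ = 0.30, CpG-dense
regions of 50–500 bp): 50/50 planted region-contrasts recovered at ≥ 0.8
sensitivity and precision, 19/20 single-region seeds at Jaccard ≥ 0.8, and
0 false regions in ~1.2 × 10⁵ tested null sites.

## Differential expression

A deliberately small NB Wald pipeline: the decision rule — Bonferroni-
adjusted p < 0.05 and |log2FC| > 1 — is the contract, and the stage exists
to feed integration; there is no GLM with covariates, no LFC shrinkage, no
independent filtering.

* **Size factors**: median over genes (with all-nonzero counts) of
  count/geometric-mean, rescaled to geometric mean 1; planted factors are
  recovered within 5%.
* **Dispersion**: pooled within-group method of moments
  (Var = μ + αμ²), shrunk on the log scale toward the trend
  α(μ) = a₀ + a₁/μ fitted by iteratively reweighted least squares with
  gamma-like weights; clip [10⁻⁸, 10].
* **Wald**: log2FC = log₂((ȳ_A + ½)/(ȳ_B + ½)) on normalized counts
  (pseudo-count ½ tolerates zeros, configurable); the SE is the
  delta-method variance of each group mean,
  Var(ȳ_g) = Σᵢ(μ/sᵢ + αμ²)/n². All-zero genes are excluded from testing
  and from the Bonferroni family size G.

## The synthetic-data generator

The generator emulates the *shape* of a three-stage (4M/6M/10M), three-
replicate bisulfite + expression study, at desk scale:

* CpG dyads as a Poisson process (default 100 dyads/kb — both strand
  cytosines emitted as separate rows, matching the CX-report default and
  the CpG-dense character of RRBS-captured fragments); 2% of cytosines in
  CHG/CHH context at near-zero methylation, so > 97% of methylated calls
  land in CG context.
* Per-site depth ~ NB(mean 30, dispersion 0.2) — the source studies report
  total reads, not per-site depth, so this is a free simulator choice.
* Methylated counts ~ beta-binomial(μ, φ = 0.05) with μ set by the site's
  highest-priority feature (defaults ordered UTR5 < promoter < CGI <
  shore < UTR3 < exon < intron < repeat, echoing the published feature
  ordering), optionally shifted per stage (`stage_shift`) to emulate the
  late-gestation methylation rise in promoters and introns.
* Observed methylation is μ + (1−μ)·conversion_failure
  (default 0.0059 ⇒ a 99.41% conversion rate); the control chromosome
  ("lambda", excluded from all genomic summaries) is truly unmethylated.
* Planted DMRs: 50–500 bp intervals, |Δ| = 0.30, placed non-overlapping
  (1 kb padding) at CpG-dense positions (≥ 80% of the expected site count
  — a sparse interval cannot express a testable effect at this depth),
  with the shift direction chosen by baseline headroom so the full |Δ| is
  realized rather than clipped. Each interval shifts one stage, so it is
  differential in the two comparisons involving that stage — which also
  reproduces the phenomenon of genes carrying DMRs in more than one
  comparison.
* Expression: counts ~ NB(mean·sf·2^(lfc·indicator), α = 0.05), size
  factors U(0.7, 1.4), gene means log-normal around 200. Planted DEGs at
  |log2FC| = 1.5; a configurable fraction is anchored on DMR-carrying
  genes with expression sign opposite the methylation shift, creating
  concordant gene/DMR pairs for the integration stage. On the dispersion
  default: 0.05 corresponds to a ≈ 22% coefficient of variation between
  biological replicates — a realistic figure for matched tissue
  triplicates, and one at which the planted-effect benchmark (60%
  sensitivity under Bonferroni at 3 vs 3) is statistically attainable; at
  α = 0.1 the expected Wald statistic for these effects sits exactly at
  the Bonferroni threshold and no unbiased test can reach that
  sensitivity. The null-calibration harness uses α = 0.1 regardless.

What the generator does **not** emulate: read-level artifacts (PCR
duplicates, mapping bias, M-bias), non-uniform fragment capture,
correlated methylation between neighbouring CpGs under the null,
allele-specific methylation, and expression covariates/batches. Passing
benchmarks therefore demonstrate correctness of the statistics under the
stated generative model, not robustness to those real-data artifacts.

## Integration

Concordance is defined purely by fold-change signs, inferred from the
published table's Yes/No/No* pattern (the source never states the rule as
a formula): opposite nonzero signs ⇒ concordant; both strictly positive
*in a gene-body region* (exon/intron) ⇒ discordant-positive — the
starred "positive correlation between gene-body methylation and
expression" pattern; everything else, including both-negative and exact
zeros, ⇒ discordant-other. This rule reproduces all 119 fixture rows
exactly, including the two both-positive promoter rows printed as plain
"No". Gene uniqueness keys on gene id with gene-name fallback. The
fixture's `narrative_listed` column flags three concordant rows whose
genes the accompanying narrative lists omit (the table and the narrative
disagree; they affect only directions not used by the golden counts).

## Pipeline

Stages run in dependency order; each writes its outputs plus a manifest
entry (sha256 prefixes, parameters, timing). All randomness flows from the
single seed through named substreams, so reruns are bit-identical. With
`force=False` a stage whose outputs exist is skipped; the default is a
full rerun.

## Problem sizes

The test-suite and acceptance harnesses use toy genomes of one to four
chromosomes of 40–300 kb, chosen so each benchmark carries enough sites
for its statistical claim (e.g. ≥ 10⁵ tested null sites for the false-call
bound, ≥ 50,000 control cytosines for the conversion-rate check, 50
planted region-contrasts for recovery) while the whole suite completes in
about a minute.
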