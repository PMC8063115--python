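# Methods

## Scope and data model

`cosplice` analyzes paired nascent (chromatin-bound, CB) and mature (polyA)
RNA-seq against a reference annotation.  All internal coordinates are
0-based half-open; GTF/GFF3 input and output are 1-based inclusive.  Exons
are stored in ascending genomic order; transcription-direction quantities
(TSS, TES, intron ordinals, distance to TES) are derived from the strand.

Per-gene covariates (exon count, gene length, TES anchor) come from a
*representative transcript*: the longest one, ties broken by the
lexicographically smallest transcript id.  This is a convention, not a
biological claim; genes whose isoforms disagree on the TES inherit the
representative's TES.

## Constitutive introns

PIR is only defined where junction reads are unambiguous, so the unit of
analysis is the *constitutive intron*: an intron whose (start, end) interval
appears in every isoform of its gene and which overlaps no exon of any
isoform.  Single-isoform genes contribute all their introns.  The second
condition matters: an intron that is exonic in some isoform would mix
exon-body reads into the "retained" signal.

## Junction classification and PIR

Per alignment and intron, with `min_overhang` = 3 nt (default):

* **EE** — a splice gap exactly matching the intron, each flanking aligned
  block ≥ 3 nt.  Near-miss gaps (alternative splice sites) are deliberately
  `none`: they do not inform retention of the constitutive junction.
* **EI5 / EI3** — a contiguous block spanning the 5'/3' splice site
  (transcription direction) with ≥ 3 nt on both sides.  A read covering the
  entire intron contiguously would satisfy both; it is counted once, as EI5.

Only primary, uniquely mapped alignments count (MAPQ ≥ 30 by default, a
proxy for "uniquely mapped" in aligner conventions).  Strandedness defaults
to RF (dUTP libraries; read 1 antisense to the transcript) and is
configurable (`FR`, `unstranded`).  For paired-end data a fragment
increments a category at an intron at most once; the halving below corrects
double observation across the *two* boundaries of an intron, not within one.

A retained intron can be sequenced at either boundary, so

    retained = (EI5 + EI3) / 2,    PIR = retained / (retained + EE),

reported as NA when retained + EE < `min_total` (default 10; the binomial
standard error of PIR at that floor is ≈ 0.16).  Counting is a single
streaming pass with an interval tree over introns, so plain SAM input works
without an index.  Analyses gate on active genes (TPM > 1, computed from the
assay under analysis); replicate counts of a condition are summed before PIR
computation, with per-replicate PIR available for dispersion diagnostics.

Stratified analyses (`stratify_pir`) cut a covariate at empirical i/k
quantiles (k = 5 default; ties to the lower group) and compare adjacent
groups with two-sided Wilcoxon rank-sum tests; the CB-vs-polyA contrast is a
paired two-sided Wilcoxon signed-rank test over introns measured in both
assays (zeros handled by zero-splitting; identical inputs return p = 1).

## AS events and PSI

Events are enumerated from annotated isoforms only (no novel junctions):
exon skipping (identical flanking splice sites), retained intron (intron of
one isoform strictly inside an exon of another), and alternative 5'/3'
splice sites (intron pairs sharing exactly one boundary, where the
alternative region is exonic in the short-intron isoform — this last clause
keeps ES comparisons from leaking into the A5/A3 inventory).  For A5SS/A3SS
the inclusion form is the shorter intron (longer exon).  Mutually exclusive
exons and alternative first/last exons are out of scope.

PSI = Σ TPM(inclusion) / Σ TPM(inclusion ∪ exclusion), NA at zero total.
Transcript abundances are accepted as an external TSV from any quantifier;
the activity gate keeps events whose transcripts all have TPM > 1 in ≥ 3
samples.

### Differential AS

ΔPSI = mean(A) − mean(B) over replicates; an event is differential when
|ΔPSI| > 0.1 **and** p < 0.05.  The default p-value is a pooled-variance
two-sample t-test on replicate PSI values, assuming homoscedastic,
approximately normal replicate noise — exactly what the bundled generator
produces, and a reasonable approximation for replicate-level PSI away from
the [0, 1] boundaries.

A replicate-label permutation test (`method="permutation"`; exact
enumeration when there are ≤ 20 label assignments, Monte-Carlo with a fixed
seed otherwise) is provided for when the normality assumption is in doubt.
It is not the default for a structural reason: with 3 vs 3 replicates the
exact two-sided permutation p-value can never go below 2/20 = 0.1, so the
p < 0.05 cut-off is unattainable at typical replicate counts — any
per-event permutation p at 3v3 takes values in multiples of 0.1, making the
test useless at α = 0.05 regardless of effect size.  Its p-values are
super-uniform (conservative) under the null, which the test suite checks.

`overlap_calls` reports Venn counts of significant events from two assays
plus the rank correlation of the two ΔPSI vectors, both over all shared
tested events and over the union of significant ones (the relevant subset is
ambiguous in practice, so both are given).

## Expression and RNA stability

TPM uses union-exon ("mappable") gene lengths:
tpm_g = 10^6 (count_g/len_g) / Σ_j (count_j/len_j).

Stability: OLS of log2 polyA TPM on log2 CB TPM over genes with TPM > 1 in
both assays (the gate is exposed; polyA is always the response — refitting
with assays swapped is the caller's responsibility and changes the calls).
With predicted = 2^(intercept + slope·log2 CB), genes with
actual ≥ 3 × predicted are *stable*, actual ≤ predicted/3 *unstable*, else
*concordant*.  Boundaries are inclusive, with a 1e-9 relative tolerance so a
gene sitting exactly on 3× is not lost to float rounding.

Fold-change concordance between conditions uses
log2FC = log2((meanTPM₁ + c)/(meanTPM₂ + c)) with pseudocount c = 1 TPM,
Spearman correlation across assays, and a |log2FC| > 1 magnitude gate for
Venn-style overlap counts.  Statistical DEG testing (negative-binomial
shrinkage, q-values) is delegated to dedicated tools; this module reproduces
the magnitude/concordance analysis only.

## Metaprofiles

Metagene profiles anchor each gene at TSS and TES: 2-kb flanks in fixed
50-bp bins, gene body length-scaled into `body_bins` (default 100), minus
strand reversed so bin 0 is always 5'.  The per-bin statistic is the mean
per-base value per region, averaged (nanmean) across regions; flanks
running off a chromosome end become NaN bins.  Intron-anchored profiles use
fixed-width exonic flanks (150 bp in 15-bp bins by default) and a scaled
intron body; with a control track (histone H3 for ChIP marks) the per-bin
statistic is the track/control ratio (log2-ratio available), NA where the
control is zero, averaged within intron groups (typically PIR quantiles).
Flank widths and bin counts are conventions; nothing downstream depends on
their exact values.

## Synthetic data generator

The generator emulates the assumed data-generating process, not any real
genome:

* **Structure** — genes on both strands of one chromosome; exons 120–300 bp,
  introns 200–600 bp (soybean-like: mean intron ≈ 400 bp, genes a few kb),
  intergenic gaps ≥ 400 bp so reads never cross genes; GT..AG (CT..AC on
  minus) splice dinucleotides; optional second isoforms instantiating ES,
  RI, A5SS and A3SS in the first four genes.
* **Retention** — per-intron nascent retention, constant (default 0.3) or
  logistic in intron length / distance to TES; mature retention =
  nascent × (1 − completion), completion probability 0.7 by default.
  Splicing decisions are independent across introns of a molecule (no joint
  model is attempted).
* **Reads** — single-end, error-free, fixed length (80 nt default), MAPQ 60,
  RF orientation.  Gene choice ∝ abundance × transcript length; the splice
  realization of each molecule is accepted proportional to its read-start
  mass, so longer (retained) molecules yield proportionally more reads as in
  real libraries — without this weighting PIR estimates would be biased
  low.  Nascent start positions decay exponentially 5'→3' (default 0.5/kb);
  mature starts are uniform.  Base qualities are constant because nothing
  downstream uses them.
* **Truth** — per-intron retentions, per-gene abundance / stability factor
  (lognormal, sd 0.4, with optional planted 8× stable/unstable
  subpopulations) / tissue log2 fold change (sd 1.0, applied at
  transcription), and a per-read ledger of EE/EI5/EI3 status derived from
  molecule-coordinate arithmetic — an independent formulation from the
  CIGAR-based classifier, which makes the ledger a usable exact oracle.
* **Counts-level generators** — junction counts (EI5, EI3 ~ Binomial(n, r);
  EE ~ Binomial(n, 1−r)), replicate PSI tables (clipped Gaussian noise), and
  stability / fold-change TPM tables.  Analyses defined directly on counts
  or TPMs are validated at this level; read-level behavior is validated
  through the SAM path.

What the generator does **not** model: sequencing error, PCR duplicates,
fragment-length distributions, multimapping, polyA-site heterogeneity,
co-dependent splicing, or realistic sequence composition.  Tests passing on
this generator show the estimators are correct under the stated model; they
do not certify behavior under alignment artifacts real data can contain.

## Numerical and procedural choices

* Exact-gap EE matching: alternative splice-site gaps never count toward
  constitutive-junction PIR.
* Wilcoxon/ranksum tests fall back to p = 1 for fully degenerate (all-tied)
  inputs instead of erroring.
* Permutation p-values include the observed assignment in the reference set
  (never zero); Monte-Carlo p-values use the (b+1)/(m+1) estimator.
* Quantile-group ties go to the lower group; grouping requires at least k
  distinct values.
* Hypergeometric p is the inclusive upper tail `sf(k−1; N, K, n)`; BH is the
  standard step-up, clipped at 1.
* Validation problem sizes (chosen once): ~20-gene genomes at 30k reads for
  ledger identity; 200 introns × ~500 informative reads for PIR recovery;
  2,000 introns for stratification; 1,000 + 100-planted genes for
  stability; 1,000 null + 200 planted events for differential AS; 25
  intronless 10-kb genes × 150k 30-nt reads for metagene shape (short reads
  keep coverage edge effects inside the 5% flatness band).

## Known limitations

* PIR under strong 5'→3' decay carries a small downward bias: the EI3
  boundary of a retained intron sits further 3' than its EI5 boundary, so
  decay attenuates EI3 relative to EE at the same junction (≈ 0.01–0.02
  absolute at default settings).  This is a property of the estimator under
  the decay model, shared with the halving convention itself.
* bigWig coverage input is not implemented; bedGraph and SAM cover the
  text-based workflows this package targets.
* The GO mapping is used as-is; no propagation up the ontology DAG.
* Transcript abundance estimation (for PSI) is intentionally external; the
  package consumes any quantifier's TPM table.
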